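import numpy as np
import pytest

from beetlesieve import segmentation, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.SyntheticSpec(
        n_classes=3,
        n_beetles=5,
        n_edge_objects=1,
        n_debris=2,
        image_size=(200, 200),
    )


@pytest.fixture(scope="session")
def crop_dataset():
    """Segmented crops from a small synthetic dataset (3 classes).

    Session-scoped: generating + segmenting is the expensive part shared by
    the training and evaluation tests.
    """
    spec = synthetic.SyntheticSpec(
        n_classes=3,
        n_beetles=6,
        n_edge_objects=1,
        n_debris=2,
        image_size=(200, 200),
    )
    manifest, composites, truths = synthetic.generate_dataset(
        spec, batches_per_class=2, replicates_per_batch=8, seed=1
    )
    images, labels, groups = [], [], []
    for comp, _ in zip(composites, truths):
        crops, _report = segmentation.disaggregate(comp)
        for c in crops:
            images.append(c.pixels)
            labels.append(comp.label)
            groups.append(comp.group_id)
    return {
        "images": images,
        "labels": labels,
        "groups": groups,
        "spec": spec,
        "manifest": manifest,
    }
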