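import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from beetlesieve import segmentation as seg
from beetlesieve.segmentation import (
    BinaryMask,
    ChannelError,
    CompositeImage,
    DegenerateImageError,
    DetectedObject,
    binarize,
    clear_border_objects,
    disaggregate,
    extract_crops,
    filter_by_size,
    label_objects,
    otsu_threshold,
    to_grayscale,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def otsu_bruteforce(gray):
    """Exhaustive scan over all 256 candidate bins maximizing between-class
    variance; independent of the vectorized implementation."""
    hist, _ = np.histogram(gray.ravel(), bins=256, range=(0.0, 1.0))
    total = hist.sum()
    mids = (np.arange(256) + 0.5) / 256
    variances = np.full(256, -np.inf)
    for k in range(256):
        w0 = hist[: k + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * mids[: k + 1]).sum() / hist[: k + 1].sum()
        mu1 = (hist[k + 1:] * mids[k + 1:]).sum() / hist[k + 1:].sum()
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    # lowest bin within tie tolerance of the maximum
    best_k = int(np.flatnonzero(variances >= variances.max() - 1e-12)[0])
    return (best_k + 1) / 256


def bfs_components(mask, connectivity=8):
    """Flood-fill labeling oracle."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def min_sse_2partition(areas):
    """Exhaustive minimum within-cluster-SSE 2-partition of a 1-D list.

    Sorted 1-D data admits an optimal contiguous split, but we enumerate
    all splits of the sorted order to stay a pure oracle.
    """
    order = np.argsort(areas)
    s = np.asarray(areas, dtype=float)[order]
    best = None
    for cut in range(1, len(s)):
        lo, hi = s[:cut], s[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, cut)
    cut = best[1]
    keep = np.zeros(len(s), dtype=bool)
    keep[order[cut:]] = True  # larger-mean cluster
    return keep


# ---------------------------------------------------------------------------
# to_grayscale
# ---------------------------------------------------------------------------


class TestToGrayscale:
    def test_pure_white(self):
        img = np.ones((4, 4, 3))
        assert np.allclose(to_grayscale(img), 1.0)

    def test_pure_red_gives_red_weight(self):
        img = np.zeros((3, 3, 3))
        img[..., 0] = 1.0
        assert np.allclose(to_grayscale(img), 0.299)

    def test_random_image_matches_dot_product(self, rng):
        img = rng.random((8, 8, 3))
        expected = (
            0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        )
        np.testing.assert_allclose(to_grayscale(img), expected, atol=1e-12)

    def test_wrong_channels_raises(self):
        with pytest.raises(ChannelError):
            to_grayscale(np.zeros((4, 4)))
        with pytest.raises(ChannelError):
            to_grayscale(np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# otsu_threshold
# ---------------------------------------------------------------------------


class TestOtsu:
    def test_bimodal_split(self):
        gray = np.full((10, 10), 0.9)
        gray[:5] = 0.1
        t = otsu_threshold(gray)
        assert 0.1 < t < 0.9
        mask = binarize(gray, t)
        assert mask.pixels[:5].all() and not mask.pixels[5:].any()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((5, 5), 0.4))

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(100):
            gray = rng.random((16, 16))
            assert otsu_threshold(gray) == pytest.approx(
                otsu_bruteforce(gray), abs=1e-12
            )

    @settings(max_examples=30, deadline=None)
    @given(
        arrays(
            np.float64,
            (8, 8),
            elements=st.floats(0.0, 1.0, allow_nan=False, width=32),
        )
    )
    def test_property_matches_bruteforce(self, gray):
        if np.all(gray == gray.ravel()[0]):
            return
        assert otsu_threshold(gray) == otsu_bruteforce(gray)


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------


class TestBinarize:
    def test_simple(self):
        mask = binarize(np.array([[0.1, 0.9]]), 0.5)
        assert mask.pixels.tolist() == [[True, False]]

    def test_all_above_threshold_empty(self):
        mask = binarize(np.full((3, 3), 0.7), 0.7)
        assert not mask.pixels.any()

    def test_matches_elementwise_comparison(self, rng):
        gray = rng.random((20, 20))
        t = 0.42
        np.testing.assert_array_equal(binarize(gray, t).pixels, gray < t)

    def test_partition_property(self, rng):
        gray = rng.random((16, 16))
        t = otsu_threshold(gray)
        mask = binarize(gray, t)
        assert mask.pixels.sum() + (~mask.pixels).sum() == gray.size


# ---------------------------------------------------------------------------
# clear_border_objects
# ---------------------------------------------------------------------------


class TestClearBorder:
    def test_edge_blob_removed(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 0:2] = True
        out = clear_border_objects(BinaryMask(m, 0.5))
        assert not out.pixels.any()

    def test_interior_blob_kept(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 2:4] = True
        out = clear_border_objects(BinaryMask(m, 0.5))
        np.testing.assert_array_equal(out.pixels, m)

    def test_diagonal_edge_connection_removed(self):
        # blob connected to an edge pixel only diagonally -> 8-connectivity
        # treats it as one component and removes everything
        m = np.zeros((6, 6), dtype=bool)
        m[0, 0] = True
        m[1, 1] = True
        m[2, 2] = True
        out = clear_border_objects(BinaryMask(m, 0.5))
        assert not out.pixels.any()

    def test_soundness_on_random_masks(self, rng):
        for _ in range(20):
            m = rng.random((15, 15)) < 0.3
            out = clear_border_objects(BinaryMask(m, 0.5)).pixels
            border = np.zeros_like(out)
            border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
            assert not (out & border).any()
            # remaining components must match the flood-fill oracle on the
            # original mask restricted to non-border components
            for comp in bfs_components(m):
                touches = any(
                    y in (0, 14) or x in (0, 14) for y, x in comp
                )
                for y, x in comp:
                    assert out[y, x] == (not touches)


# ---------------------------------------------------------------------------
# label_objects
# ---------------------------------------------------------------------------


class TestLabelObjects:
    def test_two_squares(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1:4, 1:4] = True
        m[6:9, 6:9] = True
        objs = label_objects(BinaryMask(m, 0.5))
        assert len(objs) == 2
        assert all(o.area == 9 for o in objs)
        assert objs[0].bbox == (1, 1, 4, 4)
        assert objs[1].bbox == (6, 6, 9, 9)

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        (obj,) = label_objects(BinaryMask(m, 0.5))
        assert obj.area == 1
        assert obj.bbox == (2, 3, 3, 4)

    def test_diagonal_arms_one_component(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1, 1] = m[2, 2] = m[3, 3] = m[3, 1] = True  # meets only diagonally
        objs = label_objects(BinaryMask(m, 0.5))
        assert len(objs) == 1
        assert objs[0].area == 4

    def test_matches_bfs_oracle(self, rng):
        for _ in range(20):
            m = rng.random((12, 12)) < 0.35
            objs = label_objects(BinaryMask(m, 0.5))
            comps = bfs_components(m)
            assert len(objs) == len(comps)
            assert sorted(o.area for o in objs) == sorted(
                len(c) for c in comps
            )


# ---------------------------------------------------------------------------
# filter_by_size
# ---------------------------------------------------------------------------


def _objs(areas):
    return [
        DetectedObject(object_id=i + 1, area=a, bbox=(0, 0, 1, a))
        for i, a in enumerate(areas)
    ]


class TestFilterBySize:
    def test_spec_example(self):
        objs = filter_by_size(_objs([500, 480, 510, 3, 5]))
        assert [o.kept for o in objs] == [True, True, True, False, False]
        assert objs[3].reject_reason == "small_cluster"

    def test_single_object_kept(self):
        objs = filter_by_size(_objs([200]))
        assert objs[0].kept

    def test_all_equal_kept(self):
        objs = filter_by_size(_objs([100] * 5))
        assert all(o.kept for o in objs)

    def test_matches_min_sse_partition(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            areas = rng.integers(1, 1000, size=n).tolist()
            if len(set(areas)) == 1:
                continue
            objs = filter_by_size(_objs(areas))
            expected = min_sse_2partition(areas)
            assert [o.kept for o in objs] == expected.tolist()


# ---------------------------------------------------------------------------
# extract_crops / disaggregate
# ---------------------------------------------------------------------------


class TestExtractCrops:
    def test_halfopen_size(self, rng):
        comp = CompositeImage(pixels=rng.random((60, 80, 3)))
        obj = DetectedObject(object_id=1, area=10, bbox=(10, 20, 30, 50))
        (crop,) = extract_crops(comp, [obj])
        assert crop.pixels.shape == (20, 30, 3)
        np.testing.assert_array_equal(
            crop.pixels, comp.pixels[10:30, 20:50]
        )

    def test_zero_kept_empty(self, rng):
        comp = CompositeImage(pixels=rng.random((20, 20, 3)))
        obj = DetectedObject(
            object_id=1, area=4, bbox=(1, 1, 3, 3), kept=False,
            reject_reason="small_cluster",
        )
        assert extract_crops(comp, [obj]) == []

    def test_out_of_bounds_raises(self, rng):
        comp = CompositeImage(pixels=rng.random((10, 10, 3)))
        obj = DetectedObject(object_id=1, area=4, bbox=(5, 5, 12, 12))
        with pytest.raises(seg.BoundsError):
            extract_crops(comp, [obj])

    def test_margin_expands_within_bounds(self, rng):
        comp = CompositeImage(pixels=rng.random((30, 30, 3)))
        obj = DetectedObject(object_id=1, area=4, bbox=(10, 10, 12, 12))
        (crop,) = extract_crops(comp, [obj], margin=3)
        assert crop.bbox == (7, 7, 15, 15)


def _iou(a, b):
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    if r0 >= r1 or c0 >= c1:
        return 0.0
    inter = (r1 - r0) * (c1 - c0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


class TestDisaggregate:
    def test_blank_image_zero_crops(self):
        comp = CompositeImage(pixels=np.ones((50, 50, 3)))
        crops, report = disaggregate(comp)
        assert crops == []
        assert report.degenerate

    def test_synthetic_ground_truth(self, small_spec, rng):
        from beetlesieve import synthetic

        comp, truth = synthetic.generate_composite(small_spec, rng)
        crops, report = disaggregate(comp)
        beetles = [t for t in truth if t.role == "beetle"]
        assert len(crops) == len(beetles)
        assert report.n_edge_removed == small_spec.n_edge_objects
        assert report.n_size_rejected == small_spec.n_debris
        for t in beetles:
            best = max(_iou(t.bbox, c.bbox) for c in crops)
            assert best >= 0.9

    def test_single_beetle(self, rng):
        from beetlesieve import synthetic

        spec = synthetic.SyntheticSpec(
            n_classes=2, n_beetles=1, n_edge_objects=0, n_debris=0,
            image_size=(120, 120),
        )
        comp, truth = synthetic.generate_composite(spec, rng)
        crops, _ = disaggregate(comp)
        assert len(crops) == 1
        assert _iou(truth[0].bbox, crops[0].bbox) >= 0.9
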