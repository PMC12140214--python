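"""Ground-truthed synthetic composites and probability vectors.

Composites emulate what the segmentation pipeline actually sees: dark,
compact, textured elliptical blobs on a near-white noisy background, with
optional edge-touching objects and small debris specks. Each class has a
size / aspect / intensity / texture signature; in the "separable" regime
the signatures are far enough apart (>= 5 generator sigma on area or
intensity) that a linear classifier on (area, mean intensity) of the
ground-truth crops is near-perfect, which is the floor that makes training
tests meaningful.

Probability vectors are drawn from Dirichlet distributions in a "confident
known" regime (one large concentration) or an "ambiguous" / "ood" regime
(symmetric concentration), exercising the open-set formula's limiting
behaviors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .segmentation import CompositeImage


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap; try fewer."""


@dataclass
class ClassBlobParams:
    """Per-class blob appearance signature."""

    mean_area: float
    aspect_ratio: float = 1.8
    intensity: float = 0.25
    texture_freq: float = 4.0  # sinusoid bands across the blob's major axis
    texture_amp: float = 0.08
    color_tilt: float = 0.0  # +warm / -cool channel shift; ~0 in luminance
    area_sigma_frac: float = 0.1
    intensity_sigma: float = 0.02


@dataclass
class SyntheticSpec:
    """Parameters for one composite / dataset draw."""

    n_classes: int = 4
    class_params: list[ClassBlobParams] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    n_beetles: int = 8
    n_edge_objects: int = 2
    n_debris: int = 3
    background: float = 0.95
    noise_sigma: float = 0.02
    image_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if not self.class_params:
            self.class_params = default_class_params(self.n_classes)
        if not self.class_names:
            self.class_names = [f"GenusS{i:02d}" for i in range(self.n_classes)]
        if len(self.class_params) != self.n_classes:
            raise ValueError("class_params length must equal n_classes")
        min_area = min(p.mean_area for p in self.class_params)
        if min_area < 40:
            raise ValueError("mean blob area must be >= 40 px")


@dataclass
class TruthObject:
    bbox: tuple[int, int, int, int]  # 0-based half-open, from rendered mask
    class_name: str
    role: str  # beetle | edge | debris


def default_class_params(n_classes: int) -> list[ClassBlobParams]:
    """Separable-regime defaults.

    Areas are pairwise distinct (>= 5 sigma apart), so a linear classifier
    on (area, mean intensity) of ground-truth crops is near-perfect. The
    crop-level appearance signature is a two-factor design — intensity
    level crossed with texture frequency — so each class shares one factor
    with some other class; a class withheld from training then looks
    ambiguous (rather than extreme) to a model trained on the rest, the
    way a closely related held-out genus would.
    """
    n_levels = (n_classes + 1) // 2
    intensities = np.linspace(0.15, 0.50, max(n_levels, 2))
    tilts = (0.10, -0.10)
    freqs = (2.0, 8.0)
    areas = np.geomspace(250, 1400, n_classes)
    aspects = np.linspace(1.5, 2.2, n_classes)
    return [
        ClassBlobParams(
            mean_area=float(areas[i]),
            aspect_ratio=float(aspects[i]),
            intensity=float(intensities[i // 2]),
            texture_freq=float(freqs[i % 2]),
            texture_amp=0.12,
            color_tilt=tilts[i % 2],
            area_sigma_frac=0.06,
        )
        for i in range(n_classes)
    ]


def _render_ellipse(
    canvas: np.ndarray,
    center: tuple[float, float],
    area: float,
    aspect: float,
    angle: float,
    intensity: float,
    texture_freq: float,
    texture_amp: float,
    rng: np.random.Generator,
    color_tilt: float = 0.0,
) -> Optional[tuple[int, int, int, int]]:
    """Draw one textured dark ellipse in place; returns its tight bbox.

    Pixels outside the canvas are clipped. Returns None when no pixel lands
    inside the canvas.
    """
    h, w = canvas.shape[:2]
    a = np.sqrt(area * aspect / np.pi)  # semi-major
    b = np.sqrt(area / (aspect * np.pi))  # semi-minor
    cy, cx = center
    r_max = int(np.ceil(a)) + 1

    r0 = max(0, int(np.floor(cy - r_max)))
    r1 = min(h, int(np.ceil(cy + r_max)) + 1)
    c0 = max(0, int(np.floor(cx - r_max)))
    c1 = min(w, int(np.ceil(cx + r_max)) + 1)
    if r0 >= r1 or c0 >= c1:
        return None

    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():
        return None

    texture = texture_amp * np.sin(np.pi * texture_freq * u / a)
    jitter = rng.normal(0.0, 0.01, size=inside.shape)
    values = np.clip(intensity + texture + jitter, 0.02, 0.85)
    tilt = (color_tilt, 0.0, -color_tilt)
    for ch in range(3):
        channel = canvas[r0:r1, c0:c1, ch]
        channel[inside] = np.clip(values[inside] + tilt[ch], 0.0, 1.0)

    rows = np.any(inside, axis=1)
    cols = np.any(inside, axis=0)
    rr = np.where(rows)[0]
    cc = np.where(cols)[0]
    return (r0 + int(rr[0]), c0 + int(cc[0]), r0 + int(rr[-1]) + 1, c0 + int(cc[-1]) + 1)


def _ellipse_extents(area: float, aspect: float, angle: float) -> tuple[float, float]:
    """Axis-aligned half-extents of a rotated ellipse of given area/aspect."""
    a = np.sqrt(area * aspect / np.pi)
    b = np.sqrt(area / (aspect * np.pi))
    ca, sa = np.cos(angle), np.sin(angle)
    ex = np.sqrt((a * ca) ** 2 + (b * sa) ** 2)
    ey = np.sqrt((a * sa) ** 2 + (b * ca) ** 2)
    return float(ey), float(ex)


def _boxes_overlap(a, b, pad: int = 2) -> bool:
    return (
        a[0] - pad < b[2]
        and b[0] - pad < a[2]
        and a[1] - pad < b[3]
        and b[1] - pad < a[3]
    )


def generate_composite(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    class_index: int = 0,
    group_id: str = "",
    object_params: Optional[list[dict]] = None,
) -> tuple[CompositeImage, list[TruthObject]]:
    """Render one composite of a single class with full ground truth.

    ``object_params`` optionally fixes each beetle's sampled (area, aspect,
    intensity) so agitation replicates re-place the same physical objects.
    """
    h, w = spec.image_size
    cls = spec.class_params[class_index]
    name = spec.class_names[class_index]
    canvas = np.clip(
        spec.background + rng.normal(0.0, spec.noise_sigma, size=(h, w, 3)),
        0.0,
        1.0,
    )

    if object_params is None:
        object_params = sample_object_params(spec, class_index, rng)
    if len(object_params) != spec.n_beetles:
        raise ValueError("object_params length must equal n_beetles")

    truth: list[TruthObject] = []
    placed_boxes: list[tuple[int, int, int, int]] = []

    # edge-touching objects first: the border region is otherwise free
    for _ in range(spec.n_edge_objects):
        area = cls.mean_area
        for _try in range(300):
            angle = rng.uniform(0.0, np.pi)
            ey, ex = _ellipse_extents(area, cls.aspect_ratio, angle)
            side = int(rng.integers(0, 4))
            # centre close enough to the border that the blob must cross it
            if side == 0:
                cy = rng.uniform(-0.2, 0.6) * ey
                cx = rng.uniform(ex, w - ex)
            elif side == 1:
                cy = (h - 1) - rng.uniform(-0.2, 0.6) * ey
                cx = rng.uniform(ex, w - ex)
            elif side == 2:
                cy = rng.uniform(ey, h - ey)
                cx = rng.uniform(-0.2, 0.6) * ex
            else:
                cy = rng.uniform(ey, h - ey)
                cx = (w - 1) - rng.uniform(-0.2, 0.6) * ex
            est = (
                int(cy - ey) - 1,
                int(cx - ex) - 1,
                int(cy + ey) + 2,
                int(cx + ex) + 2,
            )
            if any(_boxes_overlap(est, b) for b in placed_boxes):
                continue
            bbox = _render_ellipse(
                canvas,
                (cy, cx),
                area,
                cls.aspect_ratio,
                angle,
                cls.intensity,
                cls.texture_freq,
                cls.texture_amp,
                rng,
                color_tilt=cls.color_tilt,
            )
            if bbox is None:
                continue
            touches = (
                bbox[0] == 0 or bbox[1] == 0 or bbox[2] == h or bbox[3] == w
            )
            if not touches:
                continue  # rendered fully interior; retry
            placed_boxes.append(est)
            truth.append(TruthObject(bbox=bbox, class_name=name, role="edge"))
            break
        else:
            raise PlacementError("could not place edge object")

    # interior beetles: non-overlapping, not touching the border
    for params in object_params:
        placed = False
        for _ in range(500):
            angle = rng.uniform(0.0, np.pi)
            ey, ex = _ellipse_extents(params["area"], params["aspect"], angle)
            my, mx = ey + 3, ex + 3
            if 2 * my >= h or 2 * mx >= w:
                continue
            cy = rng.uniform(my, h - my)
            cx = rng.uniform(mx, w - mx)
            est = (
                int(cy - ey) - 1,
                int(cx - ex) - 1,
                int(cy + ey) + 2,
                int(cx + ex) + 2,
            )
            if any(_boxes_overlap(est, b) for b in placed_boxes):
                continue
            bbox = _render_ellipse(
                canvas,
                (cy, cx),
                params["area"],
                params["aspect"],
                angle,
                params["intensity"],
                cls.texture_freq,
                cls.texture_amp,
                rng,
                color_tilt=cls.color_tilt,
            )
            if bbox is None:
                continue
            placed_boxes.append(est)
            truth.append(TruthObject(bbox=bbox, class_name=name, role="beetle"))
            placed = True
            break
        if not placed:
            raise PlacementError(
                "could not place all beetles without overlap; "
                "reduce n_beetles or enlarge image_size"
            )

    # debris: small dark specks well below the smallest beetle area
    min_beetle_area = min(p["area"] for p in object_params) if object_params else cls.mean_area
    debris_area_max = 0.08 * min_beetle_area
    for _ in range(spec.n_debris):
        for _try in range(300):
            area = rng.uniform(3.0, max(4.0, debris_area_max))
            radius = np.sqrt(area / np.pi)
            cy = rng.uniform(radius + 3, h - radius - 3)
            cx = rng.uniform(radius + 3, w - radius - 3)
            est = (
                int(cy - radius) - 1,
                int(cx - radius) - 1,
                int(cy + radius) + 2,
                int(cx + radius) + 2,
            )
            if any(_boxes_overlap(est, b) for b in placed_boxes):
                continue
            bbox = _render_ellipse(
                canvas,
                (cy, cx),
                area,
                1.0,
                0.0,
                0.2,
                0.0,
                0.0,
                rng,
            )
            if bbox is None:
                continue
            placed_boxes.append(est)
            truth.append(TruthObject(bbox=bbox, class_name=name, role="debris"))
            break
        else:
            raise PlacementError("could not place debris speck")

    composite = CompositeImage(
        pixels=canvas, label=name, group_id=group_id or f"{name}_b00"
    )
    return composite, truth


def sample_object_params(
    spec: SyntheticSpec, class_index: int, rng: np.random.Generator
) -> list[dict]:
    """Sample per-beetle (area, aspect, intensity) for one physical batch."""
    cls = spec.class_params[class_index]
    out = []
    for _ in range(spec.n_beetles):
        area = max(
            40.0,
            rng.normal(cls.mean_area, cls.area_sigma_frac * cls.mean_area),
        )
        aspect = max(1.05, rng.normal(cls.aspect_ratio, 0.1))
        intensity = float(
            np.clip(rng.normal(cls.intensity, cls.intensity_sigma), 0.03, 0.8)
        )
        out.append({"area": float(area), "aspect": float(aspect), "intensity": intensity})
    return out


def generate_dataset(
    spec: SyntheticSpec,
    batches_per_class: int,
    replicates_per_batch: int = 10,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
):
    """Generate batches of composites with replicates and a manifest.

    Each batch is one class; its ``replicates_per_batch`` composites share a
    ``group_id`` and re-place the same sampled objects at fresh positions
    and orientations (emulating dish agitation between photographs).

    Returns ``(manifest DataFrame, composites, truths)`` where row *i* of
    the manifest describes ``composites[i]``.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(seed)

    rows = []
    composites: list[CompositeImage] = []
    truths: list[list[TruthObject]] = []
    for ci, name in enumerate(spec.class_names):
        for b in range(batches_per_class):
            group_id = f"{name}_b{b:02d}"
            object_params = sample_object_params(spec, ci, rng)
            for r in range(replicates_per_batch):
                comp, truth = generate_composite(
                    spec, rng, class_index=ci, group_id=group_id,
                    object_params=object_params,
                )
                fname = f"{name}_b{b:02d}_r{r:02d}.png"
                comp.source_path = fname
                composites.append(comp)
                truths.append(truth)
                rows.append(
                    {
                        "image_path": fname,
                        "label": name,
                        "group_id": group_id,
                    }
                )
    manifest = pd.DataFrame(rows)
    return manifest, composites, truths


def generate_probability_vectors(
    n: int,
    n_classes: int,
    regime: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw probability vectors with controlled structure.

    ``confident``: Dirichlet with one large concentration (alpha_true = 50,
    others 0.5); the true class index is drawn uniformly per vector.
    ``ambiguous`` / ``ood``: symmetric Dirichlet(alpha = 5).

    Returns ``(P, true_class)`` where true_class is -1 for the
    ambiguous/ood regimes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime == "confident":
        true = rng.integers(0, n_classes, size=n)
        alpha = np.full((n, n_classes), 0.5)
        alpha[np.arange(n), true] = 50.0
        p = np.empty((n, n_classes))
        for i in range(n):
            p[i] = rng.dirichlet(alpha[i])
        return p, true
    if regime in ("ambiguous", "ood"):
        p = rng.dirichlet(np.full(n_classes, 5.0), size=n)
        return p, np.full(n, -1, dtype=int)
    raise ValueError(f"unknown regime {regime!r}")
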