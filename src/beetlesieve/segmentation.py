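"""Disaggregate a composite photograph into single-specimen crops.

The procedure is a fixed eight-step pipeline: load the colour composite,
convert to grayscale, binarize with an Otsu threshold (dark objects are
foreground), drop objects touching the image border, label the remaining
8-connected components, keep the larger of two size clusters (1-D 2-means
on pixel areas), and extract the kept bounding boxes from the original
colour image.

Conventions (fixed so that crops are bit-exact):

* coordinates are 0-based, half-open: ``row_start <= r < row_end``;
* connectivity is 8-neighbourhood throughout;
* foreground = pixels strictly below the threshold (dark specimens on a
  light background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights used for the grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: number of histogram bins used by the Otsu threshold search
OTSU_BINS = 256


class ChannelError(ValueError):
    """Raised when an image does not have exactly three channels."""


class DegenerateImageError(ValueError):
    """Raised when an image has fewer than two distinct intensities."""


class BoundsError(ValueError):
    """Raised when a bounding box falls outside the image."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CompositeImage:
    """One multi-specimen photograph plus its label and batch group."""

    pixels: np.ndarray  # H x W x 3, float in [0, 1]
    label: str = ""
    group_id: str = ""
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ChannelError(
                f"composite image must be HxWx3, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("composite image must be at least 1x1")
        if px.dtype == np.uint8:
            px = px.astype(np.float64) / 255.0
        else:
            px = px.astype(np.float64)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Boolean foreground mask; ``True`` marks the dark specimen pixels."""

    pixels: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class DetectedObject:
    """A labelled connected component with its area and tight bbox."""

    object_id: int
    area: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), 0-based half-open
    kept: bool = True
    reject_reason: Optional[str] = None  # None | "edge" | "small_cluster"

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (0 <= r0 < r1 and 0 <= c0 < c1):
            raise ValueError(f"invalid bbox {self.bbox}")
        if self.area < 1:
            raise ValueError("area must be >= 1")


@dataclass
class BeetleCrop:
    """A single-specimen sub-image extracted from the colour composite."""

    pixels: np.ndarray
    bbox: tuple[int, int, int, int]
    parent_composite: Optional[str] = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if self.pixels.shape[:2] != (r1 - r0, c1 - c0):
            raise ValueError("crop pixel extent does not match bbox")


@dataclass
class SegmentationReport:
    """Per-composite counts recorded at each pipeline stage."""

    threshold: Optional[float]
    n_objects: int
    n_edge_removed: int
    n_size_rejected: int
    n_kept: int
    degenerate: bool = False
    reason: Optional[str] = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an HxWx3 colour array to grayscale luminance.

    Uses the BT.601 weights (0.299, 0.587, 0.114); weights sum to one so a
    uniform colour maps to the same uniform intensity.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ChannelError(f"expected HxWx3 input, got shape {image.shape}")
    return image @ GRAY_WEIGHTS


def otsu_threshold(gray: np.ndarray) -> float:
    """Otsu threshold on a 256-bin histogram over [0, 1].

    Returns the bin edge maximizing the between-class variance; ties are
    broken toward the lower threshold. Raises
    :class:`DegenerateImageError` for a constant image.
    """
    gray = np.asarray(gray, dtype=np.float64)
    values = gray.ravel()
    if values.size == 0 or np.all(values == values[0]):
        raise DegenerateImageError("image has fewer than 2 distinct intensities")

    hist, _ = np.histogram(values, bins=OTSU_BINS, range=(0.0, 1.0))
    hist = hist.astype(np.float64)
    total = hist.sum()
    p = hist / total
    bin_mids = (np.arange(OTSU_BINS) + 0.5) / OTSU_BINS

    # cumulative weight and mean of the low class for every candidate split
    w0 = np.cumsum(p)
    mu_cum = np.cumsum(p * bin_mids)
    mu_total = mu_cum[-1]

    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)

    # lowest maximizing bin; the 1e-12 slack keeps the tie-break stable on
    # plateaus (empty bins) where equal variances differ only in rounding
    k = int(np.flatnonzero(sigma_b >= sigma_b.max() - 1e-12)[0])
    return (k + 1) / OTSU_BINS


def binarize(gray: np.ndarray, threshold: float) -> BinaryMask:
    """Foreground mask: ``True`` exactly where intensity < threshold."""
    gray = np.asarray(gray, dtype=np.float64)
    return BinaryMask(pixels=gray < threshold, threshold_used=float(threshold))


def clear_border_objects(mask: BinaryMask) -> BinaryMask:
    """Remove every 8-connected component that touches the image border."""
    labels = _sk_label(mask.pixels, connectivity=2)
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border_labels = border_labels[border_labels != 0]
    cleared = mask.pixels & ~np.isin(labels, border_labels)
    return BinaryMask(pixels=cleared, threshold_used=mask.threshold_used)


def label_objects(mask: BinaryMask) -> list[DetectedObject]:
    """One :class:`DetectedObject` per 8-connected foreground component.

    Object ids follow raster-scan order of each component's first pixel,
    starting at 1.
    """
    labels = _sk_label(mask.pixels, connectivity=2)
    objects = []
    for region in regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        objects.append(
            DetectedObject(
                object_id=int(region.label),
                area=int(region.area),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
            )
        )
    objects.sort(key=lambda o: o.object_id)
    return objects


def _two_means_1d(areas: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means; returns a boolean array, True = larger-mean cluster.

    In one dimension the globally optimal 2-means clustering is a
    contiguous split of the sorted values, so the minimum within-cluster
    sum of squares can be found by scanning all n-1 splits with prefix
    sums — deterministic, no initialization sensitivity.
    """
    order = np.argsort(areas, kind="stable")
    s = areas[order]
    n = len(s)
    csum = np.cumsum(s)
    csum2 = np.cumsum(s ** 2)
    total, total2 = csum[-1], csum2[-1]

    sizes_lo = np.arange(1, n)
    sum_lo = csum[:-1]
    sum2_lo = csum2[:-1]
    sse_lo = sum2_lo - sum_lo ** 2 / sizes_lo
    sizes_hi = n - sizes_lo
    sum_hi = total - sum_lo
    sse_hi = (total2 - sum2_lo) - sum_hi ** 2 / sizes_hi
    sse = sse_lo + sse_hi

    cut = int(np.flatnonzero(sse <= sse.min() + 1e-9)[0]) + 1
    keep = np.zeros(n, dtype=bool)
    keep[order[cut:]] = True
    return keep


def filter_by_size(objects: list[DetectedObject]) -> list[DetectedObject]:
    """Keep the larger of two 1-D k-means size clusters.

    Degenerate inputs (fewer than two objects, or all areas identical) keep
    everything — the filter errs toward retaining specimens.
    """
    if len(objects) < 2:
        return objects
    areas = np.array([o.area for o in objects], dtype=np.float64)
    if np.all(areas == areas[0]):
        return objects
    keep = _two_means_1d(areas)
    for obj, k in zip(objects, keep):
        obj.kept = bool(k)
        obj.reject_reason = None if k else "small_cluster"
    return objects


def _bbox_overlaps(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def extract_crops(
    composite: CompositeImage,
    objects: list[DetectedObject],
    margin: int = 0,
) -> list[BeetleCrop]:
    """Copy each kept object's (optionally margin-padded) bbox from the
    colour composite.

    Heuristic review flags replace the original manual visual inspection:
    ``touching_another_box`` when two kept boxes overlap, ``aspect_outlier``
    when a box's aspect ratio exceeds twice the median of kept boxes.
    """
    h, w = composite.shape
    kept = [o for o in objects if o.kept]
    boxes = []
    for obj in kept:
        r0, c0, r1, c1 = obj.bbox
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise BoundsError(f"bbox {obj.bbox} outside {h}x{w} image")
        boxes.append(
            (
                max(0, r0 - margin),
                max(0, c0 - margin),
                min(h, r1 + margin),
                min(w, c1 + margin),
            )
        )

    aspects = [max(b[2] - b[0], b[3] - b[1]) / min(b[2] - b[0], b[3] - b[1]) for b in boxes]
    median_aspect = float(np.median(aspects)) if aspects else 1.0

    crops = []
    for i, box in enumerate(boxes):
        flags: set[str] = set()
        if any(_bbox_overlaps(box, other) for j, other in enumerate(boxes) if j != i):
            flags.add("touching_another_box")
        if len(boxes) >= 3 and aspects[i] > 2.0 * median_aspect:
            flags.add("aspect_outlier")
        r0, c0, r1, c1 = box
        crops.append(
            BeetleCrop(
                pixels=composite.pixels[r0:r1, c0:c1].copy(),
                bbox=box,
                parent_composite=composite.source_path,
                flags=flags,
            )
        )
    if not crops:
        logger.warning(
            "no crops extracted from composite %s", composite.source_path
        )
    return crops


def disaggregate(
    composite: CompositeImage, margin: int = 0
) -> tuple[list[BeetleCrop], SegmentationReport]:
    """Run the full eight-step pipeline on one composite.

    A degenerate (constant) image yields zero crops and a report with the
    reason recorded — it does not raise.
    """
    gray = to_grayscale(composite.pixels)
    try:
        t = otsu_threshold(gray)
    except DegenerateImageError as exc:
        logger.warning("degenerate composite %s: %s", composite.source_path, exc)
        return [], SegmentationReport(
            threshold=None,
            n_objects=0,
            n_edge_removed=0,
            n_size_rejected=0,
            n_kept=0,
            degenerate=True,
            reason=str(exc),
        )

    mask = binarize(gray, t)
    all_objects = label_objects(mask)
    cleared = clear_border_objects(mask)
    interior_objects = label_objects(cleared)
    n_edge_removed = len(all_objects) - len(interior_objects)

    filtered = filter_by_size(interior_objects)
    n_rejected = sum(1 for o in filtered if not o.kept)
    crops = extract_crops(composite, filtered, margin=margin)

    report = SegmentationReport(
        threshold=t,
        n_objects=len(all_objects),
        n_edge_removed=n_edge_removed,
        n_size_rejected=n_rejected,
        n_kept=len(crops),
    )
    logger.info(
        "segmented composite=%s threshold=%.4f objects=%d edge_removed=%d "
        "size_rejected=%d kept=%d",
        composite.source_path,
        t,
        report.n_objects,
        report.n_edge_removed,
        report.n_size_rejected,
        report.n_kept,
    )
    return crops, report
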