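"""Manifest and prediction readers/writers.

Manifests are CSV. A composite manifest needs ``image_path`` and ``label``
columns; a crop manifest needs ``crop_path``, ``composite_path`` and
``label``. In both cases a missing ``group_id`` is inferred from the
filename convention ``<class>_<batch>_<replicate>.<ext>`` (group id =
``<class>_<batch>``). Predictions are JSON-lines, one object per crop,
round-tripping at full float precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CROP_MANIFEST_COLUMNS = [
    "crop_path", "composite_path", "label", "group_id",
    "bbox_r0", "bbox_c0", "bbox_r1", "bbox_c1", "area", "flags",
]


class SchemaError(ValueError):
    """Raised when a manifest lacks a required column."""


def infer_group_id(filename: str) -> str:
    """Group id from ``<class>_<batch>_<replicate>.<ext>``."""
    stem = Path(filename).stem
    parts = stem.split("_")
    if len(parts) < 3:
        raise SchemaError(
            f"cannot infer group_id from {filename!r}; expected "
            "'<class>_<batch>_<replicate>.<ext>' or an explicit group_id column"
        )
    return "_".join(parts[:2])


def read_manifest(path: str | Path, kind: str = "composite") -> pd.DataFrame:
    """Read and validate a composite or crop manifest CSV."""
    df = pd.read_csv(path, dtype=str)
    path_col = "image_path" if kind == "composite" else "crop_path"
    for col in (path_col, "label"):
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    if "group_id" not in df.columns or df["group_id"].isna().any():
        source = df[path_col]
        df["group_id"] = [infer_group_id(p) for p in source]
        logger.info("group_id inferred from filenames for %s", path)
    if (df["group_id"].astype(str).str.len() == 0).any():
        raise SchemaError("group_id entries must be non-empty")
    return df


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG image as an HxWx3 float array in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Save a float [0, 1] array as an 8-bit PNG (deterministic bytes)."""
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0).round().astype(np.uint8))


def crop_filename(composite_path: str | Path, k: int) -> str:
    return f"{Path(composite_path).stem}__obj{k}.png"


def write_predictions(records: Iterable[dict], path: str | Path) -> None:
    """Write prediction records as JSON-lines."""
    records = list(records)
    if not records:
        raise ValueError("no prediction records to write")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_predictions(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def prediction_record(crop: str, pv, result, method: str, t: float) -> dict:
    """Flatten a (ProbabilityVector, OpenSetResult) pair into a record."""
    return {
        "crop": crop,
        "class_probabilities": {
            name: float(p) for name, p in zip(pv.class_names, pv.p)
        },
        "Pu": float(result.pu),
        "unknown_score": float(result.unknown_score),
        "decision": result.decision,
        "method": method,
        "t": float(t),
    }
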