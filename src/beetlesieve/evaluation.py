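"""Closed-set metrics and the leave-one-class-out open-set evaluation.

The open-set harness trains one model per (excluded class, fold), scores
that fold's validation crops plus every excluded-class crop, and sweeps an
ROC with "unknown" as the positive class for both scoring methods (the
unknown-probability formula and the conventional 1 - max(P) baseline).
Curves are vertically averaged over folds on a fixed FPR grid; the optimal
operating point is the curve point closest to (FPR=0, TPR=1); the weighted
F1 is computed with "unknown" as an ordinary extra label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .openset import unknown_probabilities
from .splits import kfold_group_split

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class RocCurve:
    """Paired FPR/TPR arrays with score thresholds and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, is_positive: np.ndarray) -> RocCurve:
    """ROC over all distinct score thresholds (score >= t -> positive).

    ``is_positive`` marks the positive class (here: unknown). Higher scores
    must mean "more positive". Raises when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(is_positive, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both positive and negative labels are required")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    yy = y[order].astype(np.float64)

    # last index of each run of tied scores
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(yy)[distinct]
    fps = np.cumsum(1.0 - yy)[distinct]

    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[s[0] + 1.0, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def average_roc_over_folds(
    curves: Sequence[RocCurve], grid_size: int = 101
) -> RocCurve:
    """Vertical (fixed-FPR) averaging on a regular grid; AUC recomputed."""
    if len(curves) == 0:
        raise EvaluationError("need at least one curve to average")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    thrs = []
    for c in curves:
        tprs.append(np.interp(grid, c.fpr, c.tpr))
        finite = np.isfinite(c.thresholds)
        t = np.where(finite, c.thresholds, np.nanmax(c.thresholds[finite]))
        thrs.append(np.interp(grid, c.fpr, t))
    tpr = np.mean(tprs, axis=0)
    thresholds = np.mean(thrs, axis=0)
    auc = float(np.trapezoid(tpr, grid))
    return RocCurve(fpr=grid, tpr=tpr, thresholds=thresholds, auc=auc)


def optimal_threshold(curve: RocCurve) -> float:
    """Threshold at the curve point closest to (FPR 0, TPR 1).

    Distance ties resolve to the lower threshold, favouring recall of
    unknowns.
    """
    d2 = curve.fpr ** 2 + (1.0 - curve.tpr) ** 2
    best = np.flatnonzero(d2 <= d2.min() + 1e-15)
    return float(np.min(curve.thresholds[best]))


def weighted_f1(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Support-weighted F1 with "unknown" treated as an ordinary label."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise EvaluationError("empty label lists")
    labels = sorted(set(y_true) | set(y_pred))
    return float(
        f1_score(y_true, y_pred, labels=labels, average="weighted",
                 zero_division=0)
    )


def macro_f1(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    labels = sorted(set(y_true) | set(y_pred))
    return float(
        f1_score(y_true, y_pred, labels=labels, average="macro",
                 zero_division=0)
    )


@dataclass
class OpenSetEvalReport:
    """Per (excluded class, fold) metrics plus fold-averaged curves."""

    rows: pd.DataFrame
    averaged_curves: dict  # (excluded_class, method) -> RocCurve
    overall_curves: dict  # method -> RocCurve


METHODS = ("formula", "max_prob")


def loco_evaluate(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    groups: Sequence[str],
    train_cfg,
    k: int = 5,
    t: float = 0.8,
    seed: int = 0,
    grid_size: int = 101,
    class_names: Optional[list[str]] = None,
) -> OpenSetEvalReport:
    """Leave-one-class-out open-set evaluation.

    For every (excluded class, fold) pair a model is trained on the other
    classes' out-of-fold crops only, then scored on the fold's remaining
    (known) crops plus all excluded-class crops, which carry the true label
    "unknown". Both the formula unknown probability and the 1 - max(P)
    baseline are swept into ROC curves; each pair contributes AUC, the
    optimal threshold, and the weighted F1 at that threshold.
    """
    from .training import train_classifier  # deferred: heavy import

    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups, dtype=object)
    if class_names is None:
        class_names = sorted(set(labels))
    if len(class_names) < 3:
        raise EvaluationError(
            "leave-one-class-out needs >= 3 classes so every reduced model "
            "still has >= 2"
        )

    group_labels: dict[str, str] = {}
    for g, l in zip(groups, labels):
        if group_labels.setdefault(g, l) != l:
            raise EvaluationError(f"group {g!r} spans multiple labels")
    folds = kfold_group_split(group_labels, k, seed)

    rows = []
    curves: dict[tuple[str, str], list[RocCurve]] = {
        (c, m): [] for c in class_names for m in METHODS
    }

    images = list(images)
    for ei, excluded in enumerate(class_names):
        for fi, fold in enumerate(folds):
            fold_set = set(fold)
            train_idx = [
                i for i in range(len(images))
                if groups[i] not in fold_set and labels[i] != excluded
            ]
            val_idx = [
                i for i in range(len(images))
                if groups[i] in fold_set and labels[i] != excluded
            ]
            unk_idx = [i for i in range(len(images)) if labels[i] == excluded]

            train_labels = labels[train_idx]
            assert excluded not in set(train_labels), "leakage: excluded class in training"
            known_classes = [c for c in class_names if c != excluded]

            cfg = replace(train_cfg, seed=seed + 1000 * ei + fi)
            model, _ = train_classifier(
                [images[i] for i in train_idx],
                list(train_labels),
                cfg,
                class_names=known_classes,
            )

            eval_idx = val_idx + unk_idx
            x_eval = [images[i] for i in eval_idx]
            probs = np.stack([pv.p for pv in _predict(model, x_eval)])
            is_unknown = np.array(
                [labels[i] == excluded for i in eval_idx], dtype=bool
            )
            y_true = [
                "unknown" if labels[i] == excluded else str(labels[i])
                for i in eval_idx
            ]

            scores = {
                "formula": unknown_probabilities(probs, t),
                "max_prob": 1.0 - probs.max(axis=1),
            }
            row = {"excluded_class": excluded, "fold": fi + 1}
            for method in METHODS:
                curve = roc_curve(scores[method], is_unknown)
                thr = optimal_threshold(curve)
                pred = [
                    "unknown" if s >= thr else known_classes[int(np.argmax(p))]
                    for s, p in zip(scores[method], probs)
                ]
                row[f"auc_{method}"] = curve.auc
                row[f"optimal_threshold_{method}"] = thr
                row[f"weighted_f1_{method}"] = weighted_f1(y_true, pred)
                curves[(excluded, method)].append(curve)
            rows.append(row)
            logger.info(
                "loco excluded=%s fold=%d auc_formula=%.3f auc_max_prob=%.3f",
                excluded, fi + 1, row["auc_formula"], row["auc_max_prob"],
            )

    averaged = {
        key: average_roc_over_folds(cs, grid_size)
        for key, cs in curves.items()
    }
    overall = {
        m: average_roc_over_folds(
            [c for (cls, mm), cs in curves.items() if mm == m for c in cs],
            grid_size,
        )
        for m in METHODS
    }
    return OpenSetEvalReport(
        rows=pd.DataFrame(rows), averaged_curves=averaged, overall_curves=overall
    )


def _predict(model, images):
    from .training import predict

    return predict(model, images)
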