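"""Leakage-free grouped, class-stratified splitting.

All replicate photographs of one physical batch (one dish, agitated and
re-photographed) share a ``group_id`` and are always assigned whole to one
side of any split, so the same individual can never appear in both a
training and an evaluation partition.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class SplitError(ValueError):
    """Raised for an empty manifest or an infeasible split request."""


def _groups_by_class(group_labels: Mapping[str, str]) -> dict[str, list[str]]:
    by_class: dict[str, list[str]] = defaultdict(list)
    for gid in sorted(group_labels):
        by_class[group_labels[gid]].append(gid)
    return dict(by_class)


def stratified_group_test_split(
    group_labels: Mapping[str, str],
    test_frac: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Split group ids into (train, test) preserving per-class ratios.

    Parameters
    ----------
    group_labels
        Mapping ``group_id -> class label``; one entry per group.
    test_frac
        Fraction of groups placed in the test partition, in (0, 1).
    seed
        Seed for the uniform within-class selection.

    Per-class test counts follow largest-remainder rounding of
    ``test_frac * n_groups(class)`` toward a global total of
    ``round(test_frac * n_groups)``, with at least one test group per class
    where feasible. A class with a single group goes entirely to train (a
    class absent from training would be untrainable in the closed set) with
    a warning.
    """
    if not group_labels:
        raise SplitError("empty manifest: no groups to split")
    if not (0.0 < test_frac < 1.0):
        raise SplitError(f"test_frac={test_frac} must lie in (0, 1)")

    by_class = _groups_by_class(group_labels)
    rng = np.random.default_rng(seed)

    train: list[str] = []
    eligible: dict[str, list[str]] = {}
    for cls, gids in sorted(by_class.items()):
        if len(gids) < 2:
            logger.warning(
                "class %r has a single group; assigning it to train", cls
            )
            train.extend(gids)
        else:
            eligible[cls] = gids

    if not eligible:
        raise SplitError("no class has enough groups for a test split")

    quotas = {cls: test_frac * len(gids) for cls, gids in eligible.items()}
    counts = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    total_eligible = sum(len(g) for g in eligible.values())
    target = int(np.floor(test_frac * total_eligible + 0.5))

    # feasibility caps: at least one group must remain in train per class
    caps = {cls: len(gids) - 1 for cls, gids in eligible.items()}
    for cls in counts:
        counts[cls] = min(max(counts[cls], 1), caps[cls])

    def _remainder(cls: str) -> float:
        return quotas[cls] - np.floor(quotas[cls])

    # largest-remainder adjustment toward the global target
    order_desc = sorted(eligible, key=lambda c: (-_remainder(c), c))
    i = 0
    while sum(counts.values()) < target and i < 10 * len(order_desc):
        cls = order_desc[i % len(order_desc)]
        if counts[cls] < caps[cls]:
            counts[cls] += 1
        i += 1
    order_asc = sorted(eligible, key=lambda c: (_remainder(c), c))
    i = 0
    while sum(counts.values()) > target and i < 10 * len(order_asc):
        cls = order_asc[i % len(order_asc)]
        if counts[cls] > 1:
            counts[cls] -= 1
        i += 1

    test: list[str] = []
    for cls in sorted(eligible):
        gids = list(eligible[cls])
        pick = rng.choice(len(gids), size=counts[cls], replace=False)
        picked = {gids[j] for j in pick}
        test.extend(sorted(picked))
        train.extend(sorted(set(gids) - picked))

    return sorted(train), sorted(test)


def kfold_group_split(
    group_labels: Mapping[str, str],
    k: int,
    seed: int,
) -> list[list[str]]:
    """Partition group ids into ``k`` class-stratified folds.

    Within each class, groups are shuffled and dealt round-robin, so
    per-class counts across folds differ by at most one and no group
    appears in two folds.
    """
    if k < 2:
        raise SplitError(f"k={k} must be >= 2")
    if k > len(group_labels):
        raise SplitError(
            f"k={k} exceeds the number of groups ({len(group_labels)})"
        )

    by_class = _groups_by_class(group_labels)
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]

    start = 0
    for cls in sorted(by_class):
        gids = list(by_class[cls])
        rng.shuffle(gids)
        for j, gid in enumerate(gids):
            folds[(start + j) % k].append(gid)
        # rotate the starting fold per class so fold totals stay balanced
        start = (start + len(gids)) % k
    return [sorted(f) for f in folds]


def assign_splits(
    manifest,
    test_frac: float = 0.2,
    k: int = 5,
    seed: int = 0,
):
    """Add a ``split`` column (test / fold_1..fold_k) to a crop manifest.

    ``manifest`` is a DataFrame with ``label`` and ``group_id`` columns;
    returns a copy with the new column.
    """
    import pandas as pd  # local import keeps module lightweight

    if len(manifest) == 0:
        raise SplitError("empty manifest")
    group_labels = (
        manifest.groupby("group_id")["label"].first().to_dict()
    )
    train_groups, test_groups = stratified_group_test_split(
        group_labels, test_frac, seed
    )
    train_labels = {g: group_labels[g] for g in train_groups}
    folds = kfold_group_split(train_labels, k, seed)

    split_of: dict[str, str] = {g: "test" for g in test_groups}
    for i, fold in enumerate(folds, start=1):
        for g in fold:
            split_of[g] = f"fold_{i}"

    out = manifest.copy()
    out["split"] = out["group_id"].map(split_of)
    if out["split"].isna().any():
        missing = sorted(out.loc[out["split"].isna(), "group_id"].unique())
        raise SplitError(f"groups without split assignment: {missing}")
    return pd.DataFrame(out)
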