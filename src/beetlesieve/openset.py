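"""Unknown-class (out-of-class) probability scoring.

Given an n-class probability vector ``P`` and a decision-boundary scalar
``t`` in (0, 1), each probability is first transformed as

    d_i = P_i ** (1 - |P_i - t|)

which accentuates agreement between a probability and the threshold. The
unknown-class probability is then one minus the normalized mean absolute
pairwise difference (a Gini-type dispersion ratio) of the transformed
vector:

    Pu = 1 - sum_{i,j} |d_i - d_j| / (2 (n - 1) sum_j d_j)

summing over all ordered pairs. ``Pu`` is 0 for a one-hot vector (the
classifier is certain of a known class) and 1 for a uniform vector (all
classes look alike, i.e., the input is likely out of class), and lies in
[0, 1] in between by the standard Gini mean-difference bound.

The conventional baseline, thresholding ``max(P)``, is provided alongside;
both methods expose a shared ``unknown_score`` oriented so that higher
means "more unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

PROB_SUM_TOL = 1e-6


class OpenSetConfigError(ValueError):
    """Raised for an invalid threshold or method."""


@dataclass
class ProbabilityVector:
    """An n-class probability vector with class names."""

    p: np.ndarray
    class_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 1 or self.p.size < 2:
            raise ValueError("probability vector must be 1-D with n >= 2")
        if np.any(self.p < -PROB_SUM_TOL) or np.any(self.p > 1 + PROB_SUM_TOL):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(self.p.sum()) - 1.0) > PROB_SUM_TOL:
            raise ValueError(f"probabilities sum to {self.p.sum()}, expected 1")
        if self.class_names is None:
            self.class_names = [f"class_{i}" for i in range(self.p.size)]
        elif len(self.class_names) != self.p.size:
            raise ValueError("class_names length must equal n")

    @property
    def n(self) -> int:
        return self.p.size


@dataclass
class OpenSetConfig:
    """Decision configuration.

    ``t`` is the transform/decision-boundary scalar in (0, 1); ``method``
    selects the unknown score (``formula`` -> Pu, ``max_prob`` ->
    1 - max(P)); ``t_open`` is the threshold applied to Pu for the formula
    method's decision and defaults to ``t``.
    """

    t: float = 0.8
    method: str = "formula"
    t_open: Optional[float] = None

    def __post_init__(self) -> None:
        _check_threshold(self.t)
        if self.method not in ("formula", "max_prob"):
            raise OpenSetConfigError(f"unknown method {self.method!r}")
        if self.t_open is None:
            self.t_open = self.t
        else:
            _check_threshold(self.t_open)


@dataclass
class OpenSetResult:
    d: np.ndarray
    pu: float
    unknown_score: float
    decision: str
    argmax_class: str
    class_names: Sequence[str] = field(default_factory=list)


def _check_threshold(t: float) -> None:
    # t = 0 and t = 1 are rejected: at the boundary the exponent can reach
    # zero and 0**0 is undefined.
    if not (0.0 < t < 1.0):
        raise OpenSetConfigError(f"threshold t={t} must lie strictly in (0, 1)")


def transform_probabilities(p: np.ndarray, t: float) -> np.ndarray:
    """Element-wise d_i = P_i ** (1 - |P_i - t|).

    For t in (0, 1) the exponent lies in (0, 1], so d_i is well defined
    (0 ** positive = 0) and stays in [0, 1].
    """
    _check_threshold(t)
    p = np.asarray(p, dtype=np.float64)
    return np.clip(p, 0.0, 1.0) ** (1.0 - np.abs(p - t))


def _pairwise_abs_sum(d: np.ndarray) -> np.ndarray:
    """sum over all ordered pairs |d_i - d_j|, along the last axis.

    Uses the sorted-order identity sum_{i<j}(x_(j) - x_(i)) =
    sum_k (2k - n + 1) x_(k), so batches avoid an n x n intermediate.
    """
    x = np.sort(d, axis=-1)
    n = x.shape[-1]
    coef = 2.0 * np.arange(n) - (n - 1)
    return 2.0 * (x * coef).sum(axis=-1)


def unknown_probability(p: np.ndarray, t: float) -> float:
    """Unknown-class probability Pu for a single probability vector."""
    d = transform_probabilities(p, t)
    n = d.size
    denom = 2.0 * (n - 1) * d.sum()
    pu = 1.0 - _pairwise_abs_sum(d) / denom
    return float(min(max(pu, 0.0), 1.0))


def unknown_probabilities(p_matrix: np.ndarray, t: float) -> np.ndarray:
    """Vectorized Pu for an (m, n) matrix of probability vectors."""
    p_matrix = np.asarray(p_matrix, dtype=np.float64)
    d = transform_probabilities(p_matrix, t)
    n = d.shape[-1]
    denom = 2.0 * (n - 1) * d.sum(axis=-1)
    pu = 1.0 - _pairwise_abs_sum(d) / denom
    return np.clip(pu, 0.0, 1.0)


def classify_openset(pv: ProbabilityVector, cfg: OpenSetConfig) -> OpenSetResult:
    """Decide known-class vs unknown for one probability vector.

    ``max_prob``: unknown iff max(P) < t, else the argmax class.
    ``formula``: unknown iff Pu >= t_open, else the argmax class.
    Argmax ties resolve to the lowest class index. Pu is reported for both
    methods.
    """
    d = transform_probabilities(pv.p, cfg.t)
    pu = unknown_probability(pv.p, cfg.t)
    max_p = float(pv.p.max())
    argmax_class = str(pv.class_names[int(np.argmax(pv.p))])

    if cfg.method == "max_prob":
        unknown_score = 1.0 - max_p
        decision = "unknown" if max_p < cfg.t else argmax_class
    else:
        unknown_score = pu
        decision = "unknown" if pu >= cfg.t_open else argmax_class

    return OpenSetResult(
        d=d,
        pu=pu,
        unknown_score=unknown_score,
        decision=decision,
        argmax_class=argmax_class,
        class_names=list(pv.class_names),
    )
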