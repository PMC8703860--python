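"""Minimum-redundancy maximum-relevance ranking (F-test correlation quotient).

Features are ranked greedily: the first pick maximizes the one-way ANOVA
F-statistic against the binary class label; each subsequent pick maximizes

    FCQ(Xi) = F(Xi, y) / mean_{Xj selected} |rho(Xi, Xj)|

where rho is Pearson's correlation.  Ties break toward the lower column
index, so the ranking is fully deterministic given the table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConstantColumnError, DegenerateLabelsError
from .features import FeatureTable

__all__ = [
    "MRMRRanking",
    "relevance_f_statistic",
    "redundancy_correlation",
    "mrmr_rank",
    "F_SENTINEL",
]

#: Finite stand-in for an infinite F under perfect within-class separation
#: (zero within-class variance), keeping the greedy ordering well defined.
F_SENTINEL = 1e12

#: Floor on the mean-|rho| denominator so FCQ scores stay finite.
_RHO_FLOOR = 1e-12


@dataclass(frozen=True)
class MRMRRanking:
    """Greedy FCQ selection order with per-step scores."""

    order: np.ndarray
    scores: np.ndarray
    pool_size: int

    def __post_init__(self):
        order = np.asarray(self.order, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        if order.shape != scores.shape or order.ndim != 1:
            raise ValueError("order and scores must be 1-D of equal length")
        if len(np.unique(order)) != order.size:
            raise ValueError("ranking indices must be unique")
        if not np.all(np.isfinite(scores)):
            raise ValueError("ranking scores must be finite")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "scores", scores)

    def to_json(self, path, feature_names: list[str] | None = None) -> None:
        payload = {
            "order": self.order.tolist(),
            "scores": self.scores.tolist(),
            "pool_size": int(self.pool_size),
        }
        if feature_names is not None:
            payload["names"] = [feature_names[i] for i in self.order]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MRMRRanking":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.asarray(payload["order"]),
            np.asarray(payload["scores"]),
            int(payload["pool_size"]),
        )


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(
            f"need exactly two classes, got {classes.tolist()}"
        )
    return y == classes[1]


def _f_statistics(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for every column of X against binary y (vectorized)."""
    pos = _check_binary(y)
    g1, g0 = X[pos], X[~pos]
    n1, n0 = len(g1), len(g0)
    n = n1 + n0
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    grand = X.mean(axis=0)
    ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ssw = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / (n - 2))
    # Perfect separation: zero within-class variance with a real mean gap.
    f = np.where((ssw == 0) & (ssb > 0), F_SENTINEL, f)
    f = np.where((ssw == 0) & (ssb <= 0), 0.0, f)
    return f


def relevance_f_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA F between the two class-conditional samples of ``x``.

    Perfect separation (zero within-class variance) returns the finite
    sentinel :data:`F_SENTINEL` instead of infinity.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    return float(_f_statistics(x, np.asarray(y))[0])


def redundancy_correlation(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation between two feature columns (in [-1, 1])."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.std() == 0.0 or x2.std() == 0.0:
        raise ConstantColumnError("correlation undefined for a constant column")
    return float(np.corrcoef(x1, x2)[0, 1])


def mrmr_rank(table: FeatureTable, pool_size: int | None = None) -> MRMRRanking:
    """Greedy FCQ ranking of the table's columns.

    Parameters
    ----------
    pool_size : int, optional
        Number of features to retain.  Defaults to ``ceil(0.6 * m)``.

    Notes
    -----
    The first pick uses relevance only (the mean |rho| over an empty set is
    undefined).  Constant columns get F = 0 and a redundancy of 0 against
    every other column, so they sink to the bottom without raising.
    """
    if table.y is None:
        raise DegenerateLabelsError("mrmr_rank needs a labeled table")
    m = table.n_features
    if pool_size is None:
        pool_size = min(m, math.ceil(0.6 * m))
    if not 1 <= pool_size <= m:
        raise ValueError(f"pool_size must be in [1, {m}], got {pool_size}")

    F = _f_statistics(table.X, table.y)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(table.X, rowvar=False)
    corr = np.atleast_2d(corr)
    abs_corr = np.abs(np.nan_to_num(corr, nan=0.0))

    order: list[int] = []
    scores: list[float] = []
    remaining = np.ones(m, dtype=bool)

    first = int(np.argmax(F))  # argmax takes the lowest index on ties
    order.append(first)
    scores.append(float(F[first]))
    remaining[first] = False

    while len(order) < pool_size:
        cand = np.flatnonzero(remaining)
        mean_red = abs_corr[np.ix_(cand, order)].mean(axis=1)
        fcq = F[cand] / np.maximum(mean_red, _RHO_FLOOR)
        best = int(cand[np.argmax(fcq)])
        order.append(best)
        scores.append(float(fcq[np.argmax(fcq)]))
        remaining[best] = False

    return MRMRRanking(np.asarray(order), np.asarray(scores), pool_size)
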