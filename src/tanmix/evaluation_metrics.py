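"""Evaluation statistics: W1, ISE, MSE, KL, SHD, Wilcoxon signed-rank, BEC.

Density metrics compare a true and an estimated density on a shared grid
(``DensityComparison``); the 1-Wasserstein distance is the CDF-difference
integral, computed exactly in 1-D and extended to d >= 2 as the mean of the
coordinate-wise marginal W1 (the cheapest faithful extension of the 1-D
formula; stated in all reports).  Structure metrics operate on undirected 0/1
adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DensityComparison",
    "w1",
    "ise",
    "mse",
    "kl",
    "shd",
    "wilcoxon_signed_rank",
    "bec",
]

KL_FLOOR = 1e-12


@dataclass
class DensityComparison:
    """True and estimated density values tabulated on one shared grid."""

    grid: np.ndarray
    true_values: np.ndarray
    est_values: np.ndarray
    cell_volume: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.true_values = np.asarray(self.true_values, dtype=float)
        self.est_values = np.asarray(self.est_values, dtype=float)
        if self.true_values.shape != self.est_values.shape:
            raise ValueError("true/est value shapes differ")
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")
        for name, v in (("true", self.true_values), ("est", self.est_values)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} density values are not all finite")
            if np.any(v < 0):
                raise ValueError(f"{name} density has negative values")


def _draw(side, m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Normalise a W1 argument to (points (m, d), optional weights)."""
    if isinstance(side, tuple) and len(side) == 2:
        locs, wts = side
        return np.atleast_2d(np.asarray(locs, dtype=float)), np.asarray(wts, dtype=float)
    if hasattr(side, "sample"):
        return np.atleast_2d(np.asarray(side.sample(m, rng), dtype=float)), None
    if callable(side):
        return np.atleast_2d(np.asarray(side(m, rng), dtype=float)), None
    arr = np.asarray(side, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample passed to w1")
    return np.atleast_2d(arr.reshape(arr.shape[0], -1) if arr.ndim > 1 else arr[:, None]), None


def w1(true_side, est_side, m: int = 100_000,
       rng: np.random.Generator | None = None) -> float:
    """1-Wasserstein distance, int |F_true(x) - F_est(x)| dx.

    Each side may be: an (n,) / (n, d) sample array, a ``(locations,
    weights)`` pair encoding a discrete measure, an object with
    ``sample(n, rng)``, or a callable ``f(n, rng) -> sample``.  1-D is exact
    (sorted-sample / weighted-CDF matching); for d >= 2 the mean of the
    coordinate-wise marginal distances is reported.
    """
    rng = rng or np.random.default_rng(0)
    A, wa = _draw(true_side, m, rng)
    B, wb = _draw(est_side, m, rng)
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch between the two sides")
    vals = [
        stats.wasserstein_distance(A[:, k], B[:, k], u_weights=wa, v_weights=wb)
        for k in range(A.shape[1])
    ]
    return float(np.mean(vals))


def ise(cmp: DensityComparison) -> float:
    """Integrated squared error, cell_volume * sum (est - true)^2."""
    d = cmp.est_values - cmp.true_values
    return float(cmp.cell_volume * np.sum(d * d))


def mse(cmp: DensityComparison) -> float:
    """Mean squared error of the density values over the grid."""
    d = cmp.est_values - cmp.true_values
    return float(np.mean(d * d))


def kl(cmp: DensityComparison) -> float:
    """KL(true || est) on the grid, with the estimate floored at 1e-12."""
    p = cmp.true_values
    q = np.maximum(cmp.est_values, KL_FLOOR)
    mask = p > 0
    return float(
        cmp.cell_volume * np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask])))
    )


def _check_adjacency(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.array_equal(a, a.T):
        raise ValueError(f"{name} is not symmetric")
    return a


def shd(a_true: np.ndarray, a_est: np.ndarray) -> int:
    """Structural Hamming distance: upper-triangle edge disagreements."""
    a = _check_adjacency(a_true, "a_true")
    b = _check_adjacency(a_est, "a_est")
    if a.shape != b.shape:
        raise ValueError("adjacency shapes differ")
    iu = np.triu_indices(a.shape[0], k=1)
    return int(np.sum((a[iu] != 0) != (b[iu] != 0)))


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, W = min(W+, W-).

    Zero differences are dropped, ties get average ranks; the null
    distribution is exact for <= 25 nonzero pairs without ties, otherwise a
    normal approximation with continuity correction is used.  All-zero
    differences are the degenerate case: W is reported as NaN with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return float("nan"), 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return W, float(res.pvalue)


def bec(learned_structures, edge: tuple[int, int]) -> float:
    """Bootstrap edge consistency: fraction of structures containing an edge."""
    if not learned_structures:
        raise ValueError("need at least one structure")
    i, j = edge
    hits = 0
    shape = None
    for a in learned_structures:
        a = _check_adjacency(a, "structure")
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError("structures have differing sizes")
        hits += int(a[i, j] != 0)
    return hits / len(learned_structures)
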