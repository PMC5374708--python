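"""Stochastic analysis of the pruned lexicographic search cost.

Let ``f(l, theta)`` be the probability that one normal-cell model shows
sensitivity <= theta under a uniformly random inhibition of ``l`` targets
(estimated empirically by Monte-Carlo sampling of l-subsets, pooling the
cell models).  With P normal models assumed independent and identically
distributed:

* worst case: ``g_wco(l, theta) = f(l, theta)^P`` — the chance the maximum
  over P cells stays within the ceiling;
* best expected: the density of the per-cell sensitivity is self-convolved
  P-1 times to get the density of the sum, rescaled to the mean, and
  integrated: ``g_beo(l, theta) = CDF_mean(theta)``.

The search is modeled as stopping at level ``i`` (subset size) when a random
i-subset first exceeds the ceiling: ``P(L_i) = g(i-1) - g(i)`` with
``g(0) = 1``.  Stopping at level ``i`` means roughly ``sum_{j<=i} C(T, j)``
subsets were examined, so the expected savings over exhaustive enumeration
is ``E(S) = sum_i P(L_i) [2^T - sum_{j<=i} C(T, j)]`` and the expected
search count is its complement; the two sum to 2^T exactly.

This level-wise model ignores that pruning happens branch by branch, so it
is an approximation of the true pruned-tree cost; empirically it tracks the
mean observed evaluation count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._batch import MASK_DTYPE, _make_bank
from .objectives import BEO, WCO

__all__ = [
    "CdfCurve",
    "AnalysisCurves",
    "default_grid",
    "estimate_cdf",
    "g_wco",
    "g_beo",
    "curve_at_theta",
    "stop_probabilities",
    "expected_savings",
    "expected_searches",
    "analyze",
]


def default_grid(points: int = 1001) -> np.ndarray:
    return np.linspace(0.0, 1.0, points)


@dataclass(frozen=True)
class CdfCurve:
    """Empirical CDFs f(l, theta) of sensitivity after l random inhibitions.

    ``f[i, j]`` is the pooled probability, over the supplied cell models,
    that sensitivity <= grid[j] given a uniformly random inhibition of
    ``levels[i]`` targets.
    """

    levels: np.ndarray  # subset sizes l = 1..T
    grid: np.ndarray
    f: np.ndarray  # (T, len(grid))
    reps: int

    @property
    def n_targets(self) -> int:
        return int(self.levels[-1])


def random_subset_masks(
    n_targets: int, size: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """``reps`` uniformly random size-``size`` subsets as bit masks."""
    u = rng.random((reps, n_targets))
    idx = np.argpartition(u, size - 1, axis=1)[:, :size].astype(MASK_DTYPE)
    return np.bitwise_or.reduce(MASK_DTYPE(1) << idx, axis=1)


def estimate_cdf(
    models: Sequence,
    reps: int = 300_000,
    rng: Optional[np.random.Generator] = None,
    grid: Optional[np.ndarray] = None,
) -> CdfCurve:
    """Monte-Carlo estimate of f(l, theta) for l = 1..T, pooling all models.

    For each level l, ``reps`` random l-subsets are drawn and every model's
    sensitivity recorded; the pooled empirical CDF is evaluated on the grid.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng or np.random.default_rng()
    grid = default_grid() if grid is None else np.asarray(grid, float)
    T = models[0].n_targets
    bank = _make_bank(tuple(models), T)
    f = np.empty((T, grid.size))
    for l in range(1, T + 1):
        masks = random_subset_masks(T, l, reps, rng)
        vals = np.sort(bank.sensitivity(masks), axis=None)
        f[l - 1] = np.searchsorted(vals, grid, side="right") / vals.size
    return CdfCurve(np.arange(1, T + 1), grid, f, reps)


def _f_matrix(f) -> np.ndarray:
    return f.f if isinstance(f, CdfCurve) else np.asarray(f, float)


def g_wco(f, P: int) -> np.ndarray:
    """Probability the max over P i.i.d. cells stays within theta: f^P."""
    if P < 1:
        raise ValueError("P must be >= 1")
    return _f_matrix(f) ** P


def g_beo(f, P: int, grid: Optional[np.ndarray] = None) -> np.ndarray:
    """Probability the mean over P i.i.d. cells stays within theta.

    The discrete density on the (uniform) grid is self-convolved P-1 times to
    the density of the sum Z on [0, P]; the CDF of the mean Y = Z/P at grid
    point theta_j is the CDF of Z at P*theta_j, which lands exactly on index
    P*j of the convolved grid.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if isinstance(f, CdfCurve) and grid is None:
        grid = f.grid
    if grid is None:
        raise ValueError("g_beo needs the theta grid")
    grid = np.asarray(grid, float)
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0]):
        raise ValueError("g_beo requires a uniform theta grid")
    fm = _f_matrix(f)
    if P == 1:
        return fm.copy()
    G = grid.size
    out = np.empty_like(fm)
    pick = P * np.arange(G)
    for i in range(fm.shape[0]):
        pmf = np.diff(fm[i], prepend=0.0)
        pmf[0] = fm[i, 0]
        q = pmf
        for _ in range(P - 1):
            q = np.convolve(q, pmf)
        out[i] = np.clip(np.cumsum(q)[pick], 0.0, 1.0)
    return out


def curve_at_theta(g: np.ndarray, grid: np.ndarray, theta: float) -> np.ndarray:
    """g(l, theta) over l = 0..T at one ceiling, prepending g(0) = 1.

    The empty inhibition has zero sensitivity for circuit models, so the
    search never stops at level 0.
    """
    vals = np.array([np.interp(theta, grid, row) for row in g])
    return np.concatenate([[1.0], vals])


def stop_probabilities(g: Sequence[float], theta: Optional[float] = None) -> np.ndarray:
    """P(L_i) = g(i-1) - g(i) for i = 1..T, from g over levels 0..T.

    ``theta`` is accepted for symmetry with curves already sliced at a
    ceiling; it is not used.  Monte-Carlo noise can make g non-monotone in
    l; negative differences are floored at zero with a warning.
    """
    g = np.asarray(g, float)
    p = g[:-1] - g[1:]
    if (p < 0).any():
        warnings.warn(
            "g(l, theta) is not nonincreasing in l; flooring negative stop "
            "probabilities at 0 (Monte-Carlo noise)",
            stacklevel=2,
        )
        p = np.maximum(p, 0.0)
    return p


def _cum_binom(T: int) -> np.ndarray:
    return np.cumsum([math.comb(T, j) for j in range(T + 1)], dtype=float)


def expected_savings(g: Sequence[float], T: int, theta: Optional[float] = None) -> float:
    """Expected subset evaluations avoided relative to exhaustive 2^T."""
    g = np.asarray(g, float)
    if g.size != T + 1:
        raise ValueError("g must cover levels 0..T")
    p = stop_probabilities(g)
    cum = _cum_binom(T)
    return float(np.sum(p * (2.0**T - cum[1:])))


def expected_searches(g: Sequence[float], T: int, theta: Optional[float] = None) -> float:
    """Predicted number of subset evaluations for the pruned search."""
    g = np.asarray(g, float)
    if g.size != T + 1:
        raise ValueError("g must cover levels 0..T")
    p = stop_probabilities(g)
    cum = _cum_binom(T)
    return float(np.sum(p * cum[1:]) + g[-1] * 2.0**T)


@dataclass(frozen=True)
class AnalysisCurves:
    """Bundled theory outputs for one mode, ceiling and cell count P."""

    mode: str
    theta: float
    P: int
    n_targets: int
    cdf: CdfCurve
    g: np.ndarray  # (T, len(grid))
    g_theta: np.ndarray  # levels 0..T at the chosen theta
    stop_probs: np.ndarray  # levels 1..T
    expected_savings: float
    expected_searches: float


def analyze(
    models: Sequence,
    *,
    mode: str = WCO,
    theta: float = 0.1,
    P: Optional[int] = None,
    reps: int = 300_000,
    rng: Optional[np.random.Generator] = None,
    grid: Optional[np.ndarray] = None,
) -> AnalysisCurves:
    """Full pipeline: empirical CDF -> g-curve -> stop levels -> expected cost.

    ``models`` are the normal-cell models whose sensitivity distribution the
    pooled CDF estimates; ``P`` defaults to their count.
    """
    if mode not in (WCO, BEO):
        raise ValueError("mode must be 'wco' or 'beo'")
    P = len(models) if P is None else P
    cdf = estimate_cdf(models, reps=reps, rng=rng, grid=grid)
    g = g_wco(cdf, P) if mode == WCO else g_beo(cdf, P)
    g_theta = curve_at_theta(g, cdf.grid, theta)
    T = cdf.n_targets
    return AnalysisCurves(
        mode=mode,
        theta=theta,
        P=P,
        n_targets=T,
        cdf=cdf,
        g=g,
        g_theta=g_theta,
        stop_probs=stop_probabilities(g_theta),
        expected_savings=expected_savings(g_theta, T),
        expected_searches=expected_searches(g_theta, T),
    )
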