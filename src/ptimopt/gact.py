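"""Genetic-algorithm-based combination therapy design (GACT).

A therapy is a chromosome of binary target inhibitions.  Fitness is
bi-objective: tumor score (min or mean sensitivity over tumor models, to be
maximized) and toxicity score (max or mean over normal models, to be
minimized).  Each generation the population is layered into Pareto fronts;
the top front breeds the offspring (uniform crossover applied with
probability ``rate_c``, then independent per-bit mutation at ``rate_m``),
offspring are merged with their parents, and the best N individuals by
(front layer, tumor score, toxicity) survive.  The final answer is the
member of the last front with the highest tumor score among those within
the toxicity ceiling.

Elitist survivor selection makes the best feasible tumor score in the
retained population nondecreasing across generations, but nothing
guarantees convergence to the global optimum; GACT is a baseline to the
exact lexicographic search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._batch import GroupEvaluator, bits_to_masks, masks_to_bits
from .lexsearch import SearchResult, _Best
from .models import ModelGroup, TargetSet
from .objectives import ObjectiveSpec, WCO

__all__ = ["GactParams", "ParetoPoint", "dominates", "pareto_front", "crossover",
           "mutate", "gact_search"]


@dataclass(frozen=True)
class GactParams:
    pop_size: int = 100
    rate_m: float = 0.2
    rate_c: float = 0.6
    total_generations: int = 400
    off_min: int = 1000
    off_max: int = 15000
    # Stop once the cumulative offspring count would pass off_max; with the
    # per-generation clamp alone the loop instead runs all generations.
    cumulative_offspring_stop: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate_m <= 1.0 and 0.0 <= self.rate_c <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.off_min > self.off_max:
            raise ValueError("off_min must not exceed off_max")
        if self.pop_size < 1 or self.total_generations < 1:
            raise ValueError("pop_size and total_generations must be positive")


@dataclass(frozen=True)
class ParetoPoint:
    """A scored therapy: tumor score to maximize, toxicity score to minimize."""

    phi: TargetSet
    tumor_score: float
    toxicity_score: float


def dominates(a: ParetoPoint, b: ParetoPoint) -> bool:
    """True iff ``a`` is at least as good in both objectives and better in one."""
    return (
        a.tumor_score >= b.tumor_score
        and a.toxicity_score <= b.toxicity_score
        and (a.tumor_score > b.tumor_score or a.toxicity_score < b.toxicity_score)
    )


def pareto_front(points: Sequence[ParetoPoint]) -> list[ParetoPoint]:
    """The non-dominated points, in input order; duplicates are all retained."""
    if not points:
        raise ValueError("pareto_front of an empty set is undefined")
    return [
        p for p in points if not any(dominates(q, p) for q in points if q is not p)
    ]


def crossover(a: TargetSet, b: TargetSet, rng: np.random.Generator) -> TargetSet:
    """Uniform crossover: each position copies from ``a`` or ``b`` with p=1/2."""
    if a.n_targets != b.n_targets:
        raise ValueError("parents must have equal length")
    take_a = rng.integers(0, 2, size=a.n_targets).astype(bool)
    return TargetSet(tuple(np.where(take_a, a.bits, b.bits).tolist()))


def mutate(a: TargetSet, rate_m: float, rng: np.random.Generator) -> TargetSet:
    """Flip each bit independently with probability ``rate_m``."""
    if not 0.0 <= rate_m <= 1.0:
        raise ValueError("rate_m must lie in [0, 1]")
    flips = rng.random(a.n_targets) < rate_m
    return TargetSet(tuple((np.asarray(a.bits) ^ flips).astype(int).tolist()))


def _front_mask(tumor: np.ndarray, tox: np.ndarray) -> np.ndarray:
    """Boolean mask of the non-dominated points (vectorized pairwise check)."""
    ge = tumor[:, None] >= tumor[None, :]
    le = tox[:, None] <= tox[None, :]
    strict = (tumor[:, None] > tumor[None, :]) | (tox[:, None] < tox[None, :])
    dom = ge & le & strict  # dom[i, j]: i dominates j
    return ~dom.any(axis=0)


def _front_layers(tumor: np.ndarray, tox: np.ndarray, need: int) -> np.ndarray:
    """Layer index per point by repeated front peeling.

    Peeling stops once ``need`` points have been assigned; the remainder get
    layer ``n`` (worse than any peeled layer), which is enough to select the
    top ``need`` survivors.
    """
    n = tumor.size
    layer = np.full(n, n, dtype=np.int64)
    remaining = np.arange(n)
    current = 0
    assigned = 0
    while remaining.size and assigned < need:
        front = _front_mask(tumor[remaining], tox[remaining])
        layer[remaining[front]] = current
        assigned += int(front.sum())
        remaining = remaining[~front]
        current += 1
    return layer


def gact_search(
    group: ModelGroup,
    spec: ObjectiveSpec,
    params: GactParams = GactParams(),
    rng: Optional[np.random.Generator] = None,
    *,
    record_history: bool = False,
) -> SearchResult:
    """Run GACT and return the best feasible therapy from the final front.

    ``evaluations`` counts every scored individual (initial population plus
    all offspring).  With ``record_history`` the result carries the best
    feasible tumor score of the retained population after each generation.
    """
    rng = rng or np.random.default_rng()
    ev = GroupEvaluator(group)
    T = group.n_targets

    def score(bits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        masks = bits_to_masks(bits)
        ts = ev.tumor_sensitivity(masks)
        nx = ev.normal_sensitivity(masks)
        if spec.mode == WCO:
            return ts.min(axis=1), nx.max(axis=1)
        return ts.mean(axis=1), nx.mean(axis=1)

    pop = rng.integers(0, 2, size=(params.pop_size, T), dtype=np.uint8)
    pop_tumor, pop_tox = score(pop)
    evaluations = params.pop_size
    history: list[float] = []
    cumulative_offspring = 0

    for _ in range(params.total_generations):
        front_idx = np.flatnonzero(_front_mask(pop_tumor, pop_tox))
        n_off = int(np.clip(2 * front_idx.size, params.off_min, params.off_max))
        if (
            params.cumulative_offspring_stop
            and cumulative_offspring + n_off > params.off_max
        ):
            break
        cumulative_offspring += n_off

        p1 = pop[front_idx[rng.integers(front_idx.size, size=n_off)]]
        p2 = pop[front_idx[rng.integers(front_idx.size, size=n_off)]]
        do_cross = rng.random(n_off) < params.rate_c
        take_b = rng.integers(0, 2, size=(n_off, T), dtype=np.uint8).astype(bool)
        children = np.where(do_cross[:, None] & take_b, p2, p1)
        children = children ^ (rng.random((n_off, T)) < params.rate_m)
        children = children.astype(np.uint8)
        child_tumor, child_tox = score(children)
        evaluations += n_off

        merged = np.concatenate([pop, children])
        merged_tumor = np.concatenate([pop_tumor, child_tumor])
        merged_tox = np.concatenate([pop_tox, child_tox])
        # collapse duplicate genomes: copies never dominate each other, so
        # they pile into the top layer and would crowd out diversity
        _, unique_idx = np.unique(bits_to_masks(merged), return_index=True)
        merged, merged_tumor, merged_tox = (
            merged[unique_idx], merged_tumor[unique_idx], merged_tox[unique_idx])
        layers = _front_layers(merged_tumor, merged_tox, need=params.pop_size)
        order = np.lexsort((merged_tox, -merged_tumor, layers))[: params.pop_size]
        keep_tumor, keep_tox = merged_tumor[order], merged_tox[order]
        # elitism for the constrained problem: the pool's best feasible point
        # always survives, so the best feasible score never degrades
        pool_feas = merged_tox <= spec.theta
        if pool_feas.any():
            j = int(np.argmax(np.where(pool_feas, merged_tumor, -np.inf)))
            kept_feas = keep_tox <= spec.theta
            kept_best = keep_tumor[kept_feas].max() if kept_feas.any() else -np.inf
            if merged_tumor[j] > kept_best:
                order[-1] = j
        pop, pop_tumor, pop_tox = merged[order], merged_tumor[order], merged_tox[order]

        if record_history:
            feas = pop_tox <= spec.theta
            history.append(float(pop_tumor[feas].max()) if feas.any() else -np.inf)

    front = _front_mask(pop_tumor, pop_tox)
    feas = front & (pop_tox <= spec.theta)
    if not feas.any():
        return SearchResult(
            TargetSet.empty(T), 0.0, evaluations, False,
            history=tuple(history) if record_history else None,
        )
    best = _Best(T)
    best.update(bits_to_masks(pop[feas]), pop_tumor[feas])
    res = best.result(evaluations, True)
    if record_history:
        res = SearchResult(
            res.best_phi, res.best_value, res.evaluations, True, tuple(history)
        )
    return res
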