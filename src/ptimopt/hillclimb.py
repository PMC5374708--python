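"""Random-restart hill climbing with toxicity-first neighbor selection.

Starts are drawn by thresholding Latin-hypercube samples of the unit cube at
0.5, giving stratified random bit strings.  From the current therapy the
algorithm sweeps all single-bit-flip neighbors; while the current set is over
the toxicity ceiling it descends toxicity (taking the least-toxic neighbor),
otherwise it ascends the tumor objective among neighbors that stay feasible.
A move is made only on strict improvement; otherwise the search restarts at
the next Latin-hypercube start.  One iteration is one neighbor sweep (T
evaluations); a restart is charged one iteration.  The best feasible therapy
seen anywhere is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import qmc

from ._batch import MASK_DTYPE, GroupEvaluator, bits_to_masks
from .lexsearch import SearchResult
from .models import ModelGroup, TargetSet
from .objectives import ObjectiveSpec, WCO

__all__ = ["HcParams", "lhs_starts", "neighbors", "hc_search"]

_START_BATCH = 64


@dataclass(frozen=True)
class HcParams:
    max_iter: int = 15000

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def lhs_starts(n_starts: int, n_targets: int, rng: np.random.Generator) -> list[TargetSet]:
    """Latin-hypercube points in [0,1]^T thresholded at 0.5 into bit strings."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    sampler = qmc.LatinHypercube(d=n_targets, rng=rng)
    pts = sampler.random(n_starts)
    return [TargetSet(tuple(int(x) for x in row >= 0.5)) for row in pts]


def neighbors(phi: TargetSet) -> list[TargetSet]:
    """All T therapies at Hamming distance one (flip each target in turn)."""
    out = []
    for i in range(phi.n_targets):
        bits = list(phi.bits)
        bits[i] ^= 1
        out.append(TargetSet(tuple(bits)))
    return out


def hc_search(
    group: ModelGroup,
    spec: ObjectiveSpec,
    params: HcParams = HcParams(),
    rng: Optional[np.random.Generator] = None,
    *,
    record_history: bool = False,
) -> SearchResult:
    """Random-restart hill climbing; returns the best feasible therapy seen."""
    rng = rng or np.random.default_rng()
    ev = GroupEvaluator(group)
    T = group.n_targets
    theta = spec.theta
    flip = MASK_DTYPE(1) << np.arange(T, dtype=MASK_DTYPE)

    start_buffer: list[int] = []

    def next_start() -> int:
        if not start_buffer:
            start_buffer.extend(
                int(m) for m in bits_to_masks(
                    np.array([s.bits for s in lhs_starts(_START_BATCH, T, rng)], np.uint8)
                )
            )
        return start_buffer.pop(0)

    def evaluate(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tox = ev.toxicity(masks, spec)
        obj = np.full(masks.size, -np.inf)
        feas = tox <= theta
        if feas.any():
            obj[feas] = ev.objective(masks[feas], spec)
        return tox, obj

    evaluations = 0
    best_value, best_mask, feasible_found = -np.inf, 0, False
    history: list[float] = []

    def note(masks: np.ndarray, obj: np.ndarray) -> None:
        nonlocal best_value, best_mask, feasible_found
        j = int(obj.argmax())
        if obj[j] > best_value:
            best_value, best_mask, feasible_found = float(obj[j]), int(masks[j]), True

    current = np.array([next_start()], MASK_DTYPE)
    cur_tox, cur_obj = evaluate(current)
    evaluations += 1
    if np.isfinite(cur_obj[0]):
        note(current, cur_obj)

    iterations = 0
    while iterations < params.max_iter:
        neigh = current[0] ^ flip
        tox, obj = evaluate(neigh)
        evaluations += T
        iterations += 1
        if np.isfinite(obj).any():
            note(neigh, obj)

        if cur_tox[0] > theta:
            j = int(tox.argmin())  # first index on ties
            improved = tox[j] < cur_tox[0]
        else:
            j = int(obj.argmax())
            improved = obj[j] > cur_obj[0]
        if improved:
            current = neigh[j : j + 1]
            cur_tox, cur_obj = tox[j : j + 1], obj[j : j + 1]
        else:
            if iterations >= params.max_iter:
                break
            iterations += 1  # a restart is charged one iteration
            current = np.array([next_start()], MASK_DTYPE)
            cur_tox, cur_obj = evaluate(current)
            evaluations += 1
            if np.isfinite(cur_obj[0]):
                note(current, cur_obj)
        if record_history:
            history.append(best_value if feasible_found else -np.inf)

    if not feasible_found:
        return SearchResult(
            TargetSet.empty(T), 0.0, evaluations, False,
            history=tuple(history) if record_history else None,
        )
    return SearchResult(
        TargetSet.from_mask(best_mask, T),
        best_value,
        evaluations,
        True,
        history=tuple(history) if record_history else None,
    )
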