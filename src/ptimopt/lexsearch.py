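"""Optimal lexicographic search with anti-monotone toxicity pruning.

The solution space of therapies over ``T`` targets is the subset lattice
{0,1}^T.  The search walks the standard lexicographic spanning tree of that
lattice: the children of a node extend it by one target whose index is
strictly greater than the node's highest inhibited index, so every subset is
reached exactly once and parents are visited before children.  Because
toxicity (max or mean sensitivity over normal models) is monotone
nondecreasing under inclusion, a node whose toxicity exceeds the ceiling
theta cannot have a feasible descendant: the node is not expanded, excising
its whole subtree from the search.

The traversal here is level-order (an explicit frontier of same-size
subsets, expanded in bulk with numpy) rather than the recursive depth-first
formulation; the visited node set, and hence the evaluation count, is
identical because pruning only depends on the node itself.

``exhaustive_search`` enumerates all 2^T subsets and serves as the oracle
against which the pruned search is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._batch import MASK_DTYPE, GroupEvaluator
from .models import ModelGroup, TargetSet
from .objectives import ObjectiveSpec, WCO

__all__ = ["SearchResult", "lex_search", "lex_search_prefixes", "exhaustive_search"]


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a therapy search.

    ``evaluations`` counts every subset whose toxicity/objective was computed,
    including the empty root.  ``feasible_found`` is False only when not even
    the empty inhibition satisfies the toxicity ceiling (possible for lookup
    PTIMs with a nonzero baseline), in which case the empty set with value 0
    is returned as a fallback.
    """

    best_phi: TargetSet
    best_value: float
    evaluations: int
    feasible_found: bool
    history: Optional[tuple] = None


def _revbits(masks: np.ndarray, n_targets: int) -> np.ndarray:
    """Bit-reversed masks; integer order of the result is 01-string order."""
    out = np.zeros(masks.shape, np.uint64)
    m = masks.astype(np.uint64)
    for i in range(n_targets):
        out |= ((m >> np.uint64(i)) & np.uint64(1)) << np.uint64(n_targets - 1 - i)
    return out


class _Best:
    """Running argmax with the tie-break: fewer targets, then smallest 01-string."""

    def __init__(self, n_targets: int):
        self.n_targets = n_targets
        self.value = -np.inf
        self.mask = 0
        self._pc = np.iinfo(np.int64).max
        self._rev = np.iinfo(np.uint64).max

    def update(self, masks: np.ndarray, values: np.ndarray) -> None:
        if masks.size == 0:
            return
        mx = float(values.max())
        if mx < self.value:
            return
        cand = masks[values == mx]
        pc = np.bitwise_count(cand.astype(np.uint64)).astype(np.int64)
        cand = cand[pc == pc.min()]
        pc_min = int(pc.min())
        rev = _revbits(cand, self.n_targets)
        j = int(rev.argmin())
        key = (-mx, pc_min, int(rev[j]))
        if key < (-self.value, self._pc, self._rev):
            self.value, self.mask, self._pc, self._rev = mx, int(cand[j]), pc_min, int(rev[j])

    def result(self, evaluations: int, feasible_found: bool) -> SearchResult:
        if not feasible_found:
            return SearchResult(
                TargetSet.empty(self.n_targets), 0.0, evaluations, False
            )
        return SearchResult(
            TargetSet.from_mask(self.mask, self.n_targets),
            self.value,
            evaluations,
            True,
        )


def _prefix_objectives(sens: np.ndarray, prefixes: Sequence[int], mode: str) -> np.ndarray:
    """Tumor objective for each leading-prefix subgroup; (n, len(prefixes))."""
    k = sens.shape[1]
    if mode == WCO:
        acc = np.minimum.accumulate(sens, axis=1)
    else:
        acc = np.cumsum(sens, axis=1) / np.arange(1, k + 1)
    return acc[:, np.asarray(prefixes) - 1]


def _lex_engine(
    group: ModelGroup,
    spec: ObjectiveSpec,
    prefixes: Sequence[int],
    chunk: int,
) -> tuple[int, list[_Best], bool]:
    ev = GroupEvaluator(group)
    T = group.n_targets
    theta = spec.theta
    bests = [_Best(T) for _ in prefixes]

    root = np.zeros(1, MASK_DTYPE)
    evaluations = 1
    feasible_found = bool(ev.toxicity(root, spec)[0] <= theta)
    if not feasible_found:
        return evaluations, bests, False

    vals0 = _prefix_objectives(ev.tumor_sensitivity(root), prefixes, spec.mode)
    for j, b in enumerate(bests):
        b.update(root, vals0[:, j])

    frontier_masks = root
    frontier_top = np.array([-1], np.int64)  # highest inhibited index per node
    while frontier_masks.size:
        counts = T - 1 - frontier_top
        keep = counts > 0
        masks, tops, counts = frontier_masks[keep], frontier_top[keep], counts[keep]
        if masks.size == 0:
            break
        total = int(counts.sum())
        # ragged arange: child bit positions tops[i]+1 .. T-1 for each parent i
        ends = np.cumsum(counts)
        offsets = np.arange(total, dtype=np.int64) - np.repeat(ends - counts, counts)
        bits = (np.repeat(tops + 1, counts) + offsets).astype(MASK_DTYPE)
        children = np.repeat(masks, counts) | (MASK_DTYPE(1) << bits)

        survivors, survivor_tops = [], []
        for lo in range(0, total, chunk):
            cm = children[lo : lo + chunk]
            cb = bits[lo : lo + chunk]
            tox = ev.toxicity(cm, spec)
            evaluations += cm.size
            feas = tox <= theta
            if not feas.any():
                continue
            fm = cm[feas]
            vals = _prefix_objectives(ev.tumor_sensitivity(fm), prefixes, spec.mode)
            for j, b in enumerate(bests):
                b.update(fm, vals[:, j])
            survivors.append(fm)
            survivor_tops.append(cb[feas].astype(np.int64))
        if survivors:
            frontier_masks = np.concatenate(survivors)
            frontier_top = np.concatenate(survivor_tops)
        else:
            break
    return evaluations, bests, True


def lex_search(
    group: ModelGroup,
    spec: ObjectiveSpec,
    *,
    max_targets: int = 30,
    chunk: int = 1 << 19,
) -> SearchResult:
    """Globally optimal therapy under the toxicity ceiling via pruned search.

    Returns the feasible inhibition maximizing the tumor objective; ties are
    broken toward fewer inhibited targets, then the smallest 01-string.
    Raises ``ValueError`` for partial lookup tables (pruning needs every
    subset evaluable) and for ``T`` beyond ``max_targets`` (the frontier is
    exponential in the worst case; raise the cap explicitly if you mean it).
    """
    if group.n_targets > max_targets:
        raise ValueError(
            f"T={group.n_targets} exceeds max_targets={max_targets}; pass a "
            "larger max_targets only if the toxicity ceiling prunes aggressively"
        )
    evaluations, bests, ok = _lex_engine(group, spec, [group.k], chunk)
    return bests[0].result(evaluations, ok)


def lex_search_prefixes(
    group: ModelGroup,
    spec: ObjectiveSpec,
    prefixes: Sequence[int],
    *,
    max_targets: int = 30,
    chunk: int = 1 << 19,
) -> list[SearchResult]:
    """One pruned search shared by several leading tumor-prefix subgroups.

    Pruning depends only on the normal models, so the searches for
    ``group.subselect(j, p)`` over the listed ``j`` visit the same nodes;
    this runs the traversal once and scores every prefix objective at each
    feasible node.  Each returned result is identical to running
    :func:`lex_search` on the corresponding subgroup.
    """
    if any(not 1 <= j <= group.k for j in prefixes):
        raise ValueError("prefixes must lie in [1, k]")
    if group.n_targets > max_targets:
        raise ValueError(f"T={group.n_targets} exceeds max_targets={max_targets}")
    evaluations, bests, ok = _lex_engine(group, spec, list(prefixes), chunk)
    return [b.result(evaluations, ok) for b in bests]


def exhaustive_search(
    group: ModelGroup,
    spec: ObjectiveSpec,
    *,
    max_targets: int = 20,
    chunk: int = 1 << 18,
) -> SearchResult:
    """Brute-force oracle: evaluate all 2^T subsets; evaluations == 2^T."""
    T = group.n_targets
    if T > max_targets:
        raise ValueError(f"refusing exhaustive enumeration for T={T} > {max_targets}")
    ev = GroupEvaluator(group)
    best = _Best(T)
    feasible_found = False
    for lo in range(0, 1 << T, chunk):
        masks = np.arange(lo, min(lo + chunk, 1 << T), dtype=MASK_DTYPE)
        feas = ev.toxicity(masks, spec) <= spec.theta
        if feas.any():
            feasible_found = True
            fm = masks[feas]
            best.update(fm, ev.objective(fm, spec))
    return best.result(1 << T, feasible_found)
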