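"""Vectorized batch evaluation of model groups on arrays of inhibition masks.

Therapies are carried as uint32 bit masks (target i on bit i).  Circuit banks
evaluate all models of one side (tumor or normal) for a whole mask array in a
few numpy operations; complete lookup PTIMs are densified into arrays indexed
by mask.  Search algorithms and the CDF estimator all go through this layer.
"""

from __future__ import annotations

import numpy as np

from .models import CircuitModel, LookupPTIM, ModelGroup
from .objectives import ObjectiveSpec, WCO

MASK_DTYPE = np.uint32


def bits_to_masks(bits: np.ndarray) -> np.ndarray:
    """(n, T) 0/1 matrix -> (n,) uint32 masks."""
    T = bits.shape[1]
    weights = (np.uint64(1) << np.arange(T, dtype=np.uint64))
    return (bits.astype(np.uint64) @ weights).astype(MASK_DTYPE)


def masks_to_bits(masks: np.ndarray, n_targets: int) -> np.ndarray:
    """(n,) masks -> (n, T) 0/1 uint8 matrix."""
    shifts = np.arange(n_targets, dtype=MASK_DTYPE)
    return ((masks[:, None] >> shifts) & 1).astype(np.uint8)


class _CircuitBank:
    """All-circuit side of a group, padded to a common block count.

    Padding blocks get mask 0 and score 0: ``(m & 0) == 0`` makes them always
    "inhibited" but the zero score makes their factor 1, a no-op.
    """

    def __init__(self, models: tuple[CircuitModel, ...]):
        n_blocks = max(len(m.blocks) for m in models)
        self.block_masks = np.zeros((len(models), n_blocks), MASK_DTYPE)
        self.scores = np.zeros((len(models), n_blocks))
        for i, m in enumerate(models):
            for j, b in enumerate(m.blocks):
                self.block_masks[i, j] = sum(1 << t for t in b.members)
                self.scores[i, j] = b.score

    def sensitivity(self, masks: np.ndarray) -> np.ndarray:
        """(n,) masks -> (n, n_models) sensitivities."""
        lam = (masks[:, None, None] & self.block_masks) == self.block_masks
        factors = np.where(lam, 1.0 - self.scores, 1.0)
        return 1.0 - factors.prod(axis=2)


class _LookupBank:
    """All-lookup side of a group, densified to (n_models, 2^T) arrays."""

    def __init__(self, models: tuple[LookupPTIM, ...], n_targets: int):
        for m in models:
            if not m.complete:
                raise ValueError(
                    f"lookup PTIM {m.label!r} is partial; searches require a "
                    "complete table over all 2^T subsets"
                )
        self.lut = np.zeros((len(models), 1 << n_targets))
        for i, m in enumerate(models):
            for mask, v in m.table.items():
                self.lut[i, mask] = v

    def sensitivity(self, masks: np.ndarray) -> np.ndarray:
        return self.lut[:, masks].T


class _MixedBank:
    """Fallback for a side mixing circuit and lookup models."""

    def __init__(self, models: tuple, n_targets: int):
        self.banks = [
            _CircuitBank((m,)) if isinstance(m, CircuitModel) else _LookupBank((m,), n_targets)
            for m in models
        ]

    def sensitivity(self, masks: np.ndarray) -> np.ndarray:
        return np.column_stack([b.sensitivity(masks)[:, 0] for b in self.banks])


def _make_bank(models: tuple, n_targets: int):
    if all(isinstance(m, CircuitModel) for m in models):
        return _CircuitBank(models)
    if all(isinstance(m, LookupPTIM) for m in models):
        return _LookupBank(models, n_targets)
    return _MixedBank(models, n_targets)


class GroupEvaluator:
    """Batch sensitivity / objective / toxicity evaluation for one group."""

    def __init__(self, group: ModelGroup):
        self.group = group
        self.n_targets = group.n_targets
        self._tumor = _make_bank(group.tumors, group.n_targets)
        self._normal = _make_bank(group.normals, group.n_targets)

    def tumor_sensitivity(self, masks: np.ndarray) -> np.ndarray:
        return self._tumor.sensitivity(np.asarray(masks, MASK_DTYPE))

    def normal_sensitivity(self, masks: np.ndarray) -> np.ndarray:
        return self._normal.sensitivity(np.asarray(masks, MASK_DTYPE))

    def toxicity(self, masks: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
        sens = self.normal_sensitivity(masks)
        return sens.max(axis=1) if spec.mode == WCO else sens.mean(axis=1)

    def objective(self, masks: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
        sens = self.tumor_sensitivity(masks)
        return sens.min(axis=1) if spec.mode == WCO else sens.mean(axis=1)
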