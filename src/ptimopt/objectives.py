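"""Tumor objectives and normal-cell toxicity under the two design modes.

WCO (worst-case optimization) maximizes the minimum sensitivity over the
tumor models while the *maximum* sensitivity over normal models stays at or
below the toxicity ceiling theta.  BEO (best-expected optimization) uses the
mean on both sides.  Since every model's sensitivity is monotone under
inclusion of the inhibition set, both toxicity aggregates are monotone too,
which is what makes superset pruning in the searches sound.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import ModelGroup, TargetSet

__all__ = ["ObjectiveSpec", "tumor_objective", "toxicity", "feasible", "WCO", "BEO"]

WCO = "wco"
BEO = "beo"


@dataclass(frozen=True)
class ObjectiveSpec:
    """Optimization mode (``"wco"`` or ``"beo"``) and toxicity ceiling theta."""

    mode: str = WCO
    theta: float = 0.1

    def __post_init__(self) -> None:
        mode = self.mode.lower()
        if mode not in (WCO, BEO):
            raise ValueError(f"mode must be 'wco' or 'beo', got {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta {self.theta} outside [0, 1]")


def tumor_objective(group: ModelGroup, phi: TargetSet, spec: ObjectiveSpec) -> float:
    """Min (WCO) or mean (BEO) sensitivity over the group's tumor models."""
    vals = [m.sensitivity(phi) for m in group.tumors]
    if spec.mode == WCO:
        return min(vals)
    return sum(vals) / len(vals)


def toxicity(group: ModelGroup, phi: TargetSet, spec: ObjectiveSpec) -> float:
    """Max (WCO) or mean (BEO) sensitivity over the group's normal models."""
    vals = [m.sensitivity(phi) for m in group.normals]
    if spec.mode == WCO:
        return max(vals)
    return sum(vals) / len(vals)


def feasible(group: ModelGroup, phi: TargetSet, spec: ObjectiveSpec) -> bool:
    """True iff toxicity is at or below theta (the boundary is feasible)."""
    return toxicity(group, phi, spec) <= spec.theta
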