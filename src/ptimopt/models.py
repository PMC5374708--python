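"""Probabilistic target inhibition maps (PTIMs) and therapy bit vectors.

A PTIM assigns every subset of drug targets an expected kill sensitivity in
[0, 1].  When every target is an oncogene, inhibiting more targets can only
keep the sensitivity the same or increase it, so a PTIM is monotone
nondecreasing under set inclusion.  Two concrete representations are
supported:

* :class:`CircuitModel` -- a tumor (or normal-cell) proliferation circuit of
  series-connected blocks of parallel targets.  A block contributes its score
  once *all* of its targets are inhibited; the overall sensitivity is
  ``1 - prod_b (1 - S_b * lambda_b)`` with ``lambda_b`` in {0, 1}.
* :class:`LookupPTIM` -- an explicit subset -> sensitivity table, e.g. a map
  inferred from a drug screen.

Conventions
-----------
Targets are 0-indexed.  A therapy is written as a 01-string whose position
``i`` refers to target ``i``, so the string ``"1100"`` over four targets
inhibits targets 0 and 1.  Internally subsets are also carried as integer
bit masks with target ``i`` on bit ``i`` (value ``1 << i``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ModelFormatError",
    "MonotonicityWarning",
    "TargetSet",
    "Block",
    "CircuitModel",
    "LookupPTIM",
    "ModelGroup",
    "block_inhibition",
    "circuit_sensitivity",
    "lookup_sensitivity",
    "tabulate_circuit",
    "read_models",
    "write_models",
    "read_lookup_tsv",
    "write_lookup_tsv",
]


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or violates an invariant."""


class MonotonicityWarning(UserWarning):
    """Issued when a lookup table violates monotonicity under inclusion."""


@dataclass(frozen=True)
class TargetSet:
    """A therapy: a fixed-length binary vector marking inhibited targets.

    ``bits[i]`` is 1 iff target ``i`` is inhibited.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("TargetSet entries must be 0 or 1")
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))

    @classmethod
    def from_indices(cls, indices: Iterable[int], n_targets: int) -> "TargetSet":
        bits = [0] * n_targets
        for i in indices:
            if not 0 <= i < n_targets:
                raise IndexError(f"target index {i} out of range for T={n_targets}")
            bits[i] = 1
        return cls(tuple(bits))

    @classmethod
    def from_string(cls, s: str) -> "TargetSet":
        if set(s) - {"0", "1"}:
            raise ValueError(f"not a 01-string: {s!r}")
        return cls(tuple(int(c) for c in s))

    @classmethod
    def from_mask(cls, mask: int, n_targets: int) -> "TargetSet":
        return cls(tuple((int(mask) >> i) & 1 for i in range(n_targets)))

    @classmethod
    def empty(cls, n_targets: int) -> "TargetSet":
        return cls((0,) * n_targets)

    @property
    def n_targets(self) -> int:
        return len(self.bits)

    @property
    def mask(self) -> int:
        return sum(b << i for i, b in enumerate(self.bits))

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    def issubset(self, other: "TargetSet") -> bool:
        return self.mask & other.mask == self.mask

    def union(self, other: "TargetSet") -> "TargetSet":
        if self.n_targets != other.n_targets:
            raise ValueError("length mismatch")
        return TargetSet.from_mask(self.mask | other.mask, self.n_targets)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class Block:
    """A parallel block: contributes ``score`` once all members are inhibited."""

    members: frozenset[int]
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(int(m) for m in self.members))
        if not self.members:
            raise ValueError("block must have at least one member target")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"block score {self.score} outside [0, 1]")


def block_inhibition(block: Block, phi: TargetSet) -> int:
    """Effective inhibition of a parallel block: min over member bits.

    Equals 1 iff every member of the block is inhibited by ``phi``.
    """
    for t in block.members:
        if t >= phi.n_targets:
            raise IndexError(f"block member {t} out of range for T={phi.n_targets}")
    return min(phi.bits[t] for t in block.members)


@dataclass(frozen=True)
class CircuitModel:
    """Series circuit of parallel target blocks approximating a PTIM.

    Sensitivity of inhibition ``phi`` is ``1 - prod_b (1 - S_b * lambda_b)``
    where ``lambda_b = 1`` iff every target of block ``b`` is in ``phi``.
    The map is monotone under inclusion and zero at the empty inhibition.
    """

    n_targets: int
    blocks: tuple[Block, ...]
    label: str = ""
    kind: str = "tumor"

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ModelFormatError(f"model {self.label!r}: empty blocks list")
        if self.kind not in ("tumor", "normal"):
            raise ModelFormatError(f"model {self.label!r}: kind must be tumor|normal")
        for b in self.blocks:
            for t in b.members:
                if not 0 <= t < self.n_targets:
                    raise ModelFormatError(
                        f"model {self.label!r}: block member {t} >= n_targets={self.n_targets}"
                    )

    def sensitivity(self, phi: TargetSet) -> float:
        return circuit_sensitivity(self, phi)


def circuit_sensitivity(model: CircuitModel, phi: TargetSet) -> float:
    """Evaluate a circuit: ``1 - prod_b (1 - S_b * block_inhibition(b, phi))``."""
    if phi.n_targets != model.n_targets:
        raise ValueError(
            f"phi has {phi.n_targets} targets, model expects {model.n_targets}"
        )
    prod = 1.0
    for b in model.blocks:
        prod *= 1.0 - b.score * block_inhibition(b, phi)
    return 1.0 - prod


@dataclass(frozen=True)
class LookupPTIM:
    """Explicit PTIM: a table from target subsets (as bit masks) to sensitivity.

    The table may be partial; search entry points reject partial tables since
    pruning guarantees need every subset to be evaluable.
    """

    n_targets: int
    table: Mapping[int, float]
    label: str = ""
    kind: str = "tumor"

    def __post_init__(self) -> None:
        tbl = {int(k): float(v) for k, v in self.table.items()}
        object.__setattr__(self, "table", tbl)
        for k, v in tbl.items():
            if not 0 <= k < (1 << self.n_targets):
                raise ModelFormatError(f"table key {k} out of range for T={self.n_targets}")
            if not 0.0 <= v <= 1.0:
                raise ModelFormatError(f"table value {v} outside [0, 1]")

    @property
    def complete(self) -> bool:
        return len(self.table) == 1 << self.n_targets

    def sensitivity(self, phi: TargetSet) -> float:
        return lookup_sensitivity(self, phi)

    def monotonicity_violations(self) -> list[tuple[int, int, float, float]]:
        """Pairs (sub, sup, v_sub, v_sup) with ``sub ⊂ sup`` and ``v_sub > v_sup``.

        Complete tables are scanned over immediate (one extra target) pairs,
        which is equivalent to full monotonicity; partial tables compare every
        pair of stored subsets, since intermediate sets may be missing.
        """
        bad = []
        if self.complete:
            for m, v in self.table.items():
                for i in range(self.n_targets):
                    bit = 1 << i
                    if m & bit:
                        continue
                    sup = m | bit
                    if v > self.table[sup] + 1e-12:
                        bad.append((m, sup, v, self.table[sup]))
        else:
            items = sorted(self.table.items())
            for a, va in items:
                for b, vb in items:
                    if a != b and a & b == a and va > vb + 1e-12:
                        bad.append((a, b, va, vb))
        return bad


def lookup_sensitivity(model: LookupPTIM, phi: TargetSet) -> float:
    if phi.n_targets != model.n_targets:
        raise ValueError(
            f"phi has {phi.n_targets} targets, model expects {model.n_targets}"
        )
    try:
        return model.table[phi.mask]
    except KeyError:
        raise KeyError(
            f"inhibition {phi.to_string()} absent from partial lookup table"
        ) from None


def tabulate_circuit(model: CircuitModel) -> LookupPTIM:
    """Enumerate all 2^T inhibitions of a circuit into a complete lookup PTIM."""
    if model.n_targets > 20:
        raise ValueError("refusing to tabulate a circuit with more than 2^20 subsets")
    table = {
        m: circuit_sensitivity(model, TargetSet.from_mask(m, model.n_targets))
        for m in range(1 << model.n_targets)
    }
    return LookupPTIM(model.n_targets, table, label=model.label, kind=model.kind)


@dataclass(frozen=True)
class ModelGroup:
    """k tumor models plus p normal models over one shared target universe."""

    tumors: tuple
    normals: tuple
    n_targets: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tumors", tuple(self.tumors))
        object.__setattr__(self, "normals", tuple(self.normals))
        if not self.tumors or not self.normals:
            raise ValueError("a group needs at least one tumor and one normal model")
        T = self.n_targets or self.tumors[0].n_targets
        object.__setattr__(self, "n_targets", T)
        for m in self.tumors + self.normals:
            if m.n_targets != T:
                raise ValueError("all models in a group must share n_targets")

    @property
    def k(self) -> int:
        return len(self.tumors)

    @property
    def p(self) -> int:
        return len(self.normals)

    def subselect(self, n_tumor: int, n_normal: int) -> "ModelGroup":
        """Keep the first ``n_tumor`` tumor and ``n_normal`` normal models."""
        if not (1 <= n_tumor <= self.k and 1 <= n_normal <= self.p):
            raise ValueError("subselection exceeds group size")
        return ModelGroup(self.tumors[:n_tumor], self.normals[:n_normal], self.n_targets)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _circuit_to_dict(m: CircuitModel) -> dict:
    return {
        "label": m.label,
        "kind": m.kind,
        "blocks": [
            {"members": sorted(b.members), "score": b.score} for b in m.blocks
        ],
    }


def _circuit_from_dict(d: dict, n_targets: int, pos: str) -> CircuitModel:
    try:
        blocks = tuple(
            Block(frozenset(b["members"]), float(b["score"])) for b in d["blocks"]
        )
        return CircuitModel(
            n_targets=n_targets,
            blocks=blocks,
            label=str(d.get("label", "")),
            kind=str(d.get("kind", "tumor")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{pos}: {exc}") from exc


def write_models(group: ModelGroup, path) -> None:
    """Serialize a circuit-model group to the JSON dialect.

    Scores are written through ``repr`` (via json), which round-trips IEEE
    doubles exactly.
    """
    payload = {
        "n_targets": group.n_targets,
        "models": [_circuit_to_dict(m) for m in group.tumors + group.normals],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_models(path) -> ModelGroup:
    """Read a circuit-model group from the JSON dialect."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        T = int(payload["n_targets"])
        entries = payload["models"]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: missing field {exc}") from exc
    tumors, normals = [], []
    for i, d in enumerate(entries):
        m = _circuit_from_dict(d, T, pos=f"{path}: models[{i}]")
        (tumors if m.kind == "tumor" else normals).append(m)
    if not tumors or not normals:
        raise ModelFormatError(f"{path}: group needs >=1 tumor and >=1 normal model")
    return ModelGroup(tuple(tumors), tuple(normals), T)


def write_lookup_tsv(model: LookupPTIM, path) -> None:
    """Write a lookup PTIM as TSV: ``targets<TAB>sensitivity`` per subset."""
    with open(path, "w") as fh:
        fh.write("targets\tsensitivity\n")
        for mask in sorted(model.table):
            s = TargetSet.from_mask(mask, model.n_targets).to_string()
            fh.write(f"{s}\t{model.table[mask]:.12g}\n")


def read_lookup_tsv(path, label: str = "", kind: str = "tumor") -> LookupPTIM:
    """Read a lookup PTIM from TSV, warning on monotonicity violations."""
    table: dict[int, float] = {}
    n_targets = None
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["targets", "sensitivity"]:
            raise ModelFormatError(f"{path}:1: expected header 'targets\\tsensitivity'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ModelFormatError(f"{path}:{lineno}: expected 2 fields")
            ts_str, val = parts
            try:
                ts = TargetSet.from_string(ts_str)
                v = float(val)
            except ValueError as exc:
                raise ModelFormatError(f"{path}:{lineno}: {exc}") from exc
            if n_targets is None:
                n_targets = ts.n_targets
            elif ts.n_targets != n_targets:
                raise ModelFormatError(f"{path}:{lineno}: inconsistent string length")
            table[ts.mask] = v
    if n_targets is None:
        raise ModelFormatError(f"{path}: empty table")
    model = LookupPTIM(n_targets, table, label=label, kind=kind)
    bad = model.monotonicity_violations()
    if bad:
        desc = "; ".join(
            f"S({TargetSet.from_mask(a, n_targets).to_string()})={va:.4g} > "
            f"S({TargetSet.from_mask(b, n_targets).to_string()})={vb:.4g}"
            for a, b, va, vb in bad[:10]
        )
        warnings.warn(
            f"{path}: lookup table violates monotone inclusion on {len(bad)} pair(s): {desc}",
            MonotonicityWarning,
            stacklevel=2,
        )
    return model
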