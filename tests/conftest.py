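import numpy as np
import pytest

from ptimopt import Block, CircuitModel, LookupPTIM, ModelGroup, TargetSet


@pytest.fixture
def example_circuit() -> CircuitModel:
    """Two series blocks: parallel {k1, k2} scored 0.95 and singleton {k3} 0.75."""
    return CircuitModel(
        n_targets=3,
        blocks=(Block(frozenset({0, 1}), 0.95), Block(frozenset({2}), 0.75)),
        label="example",
        kind="tumor",
    )


@pytest.fixture
def quiet_group() -> ModelGroup:
    """Single-block tumor {t0}@0.8 with a completely non-toxic normal model."""
    tumor = CircuitModel(1, (Block(frozenset({0}), 0.8),), kind="tumor")
    normal = LookupPTIM(1, {0: 0.0, 1: 0.0}, kind="normal")
    return ModelGroup((tumor,), (normal,), 1)


def lookup_group(n_targets: int, tox_table: dict, tum_table: dict) -> ModelGroup:
    """Assemble a one-tumor/one-normal lookup group from mask->value tables."""
    return ModelGroup(
        (LookupPTIM(n_targets, tum_table, kind="tumor"),),
        (LookupPTIM(n_targets, tox_table, kind="normal"),),
        n_targets,
    )


def random_phi(rng: np.random.Generator, n_targets: int) -> TargetSet:
    return TargetSet(tuple(int(b) for b in rng.integers(0, 2, n_targets)))
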