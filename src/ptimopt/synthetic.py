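"""Synthetic tumor/normal proliferation circuits and benchmark groups.

Each synthetic cell model is a series circuit of parallel target blocks over
a shared universe of 25 targets: five blocks per model, each holding one to
five targets drawn uniformly (all targets equiprobable, no repeats within a
block, repeats allowed across blocks), with a block score drawn uniformly
from [0.5, 1].  A benchmark is 100 independent groups of five tumor plus
five normal models; experiment harnesses then subselect nTumor/nNormal
models per group.

Block sizes are drawn uniformly from {1..max_block_size}; only the upper
bound of the block size is pinned down by the generating protocol, so the
size law is exposed in :class:`GeneratorConfig`.

Reproducibility: group ``i`` is generated from the ``i``-th spawned child of
``SeedSequence(seed)``, so any group can be regenerated in isolation and the
first groups do not change when ``n_groups`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Block, CircuitModel, ModelGroup

__all__ = ["GeneratorConfig", "generate_model", "generate_group", "generate_benchmark"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_targets: int = 25
    n_blocks: int = 5
    max_block_size: int = 5
    score_low: float = 0.5
    score_high: float = 1.0
    n_groups: int = 100
    tumors_per_group: int = 5
    normals_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_low <= self.score_high <= 1.0:
            raise ValueError("need 0 <= score_low <= score_high <= 1")
        if self.max_block_size < 1 or self.max_block_size > self.n_targets:
            raise ValueError("max_block_size must be in [1, n_targets]")
        if min(self.n_targets, self.n_blocks, self.n_groups,
               self.tumors_per_group, self.normals_per_group) < 1:
            raise ValueError("counts must be positive")


def generate_model(
    cfg: GeneratorConfig, rng: np.random.Generator, kind: str, label: str = ""
) -> CircuitModel:
    """Draw one circuit model: block sizes, members and scores as configured."""
    blocks = []
    for _ in range(cfg.n_blocks):
        size = int(rng.integers(1, cfg.max_block_size + 1))
        members = rng.choice(cfg.n_targets, size=size, replace=False)
        score = float(rng.uniform(cfg.score_low, cfg.score_high))
        blocks.append(Block(frozenset(int(t) for t in members), score))
    return CircuitModel(cfg.n_targets, tuple(blocks), label=label, kind=kind)


def generate_group(
    cfg: GeneratorConfig, rng: np.random.Generator, group_id: int = 0
) -> ModelGroup:
    """Draw one group of independent tumor and normal models."""
    tumors = tuple(
        generate_model(cfg, rng, "tumor", label=f"g{group_id:03d}/T{i}")
        for i in range(cfg.tumors_per_group)
    )
    normals = tuple(
        generate_model(cfg, rng, "normal", label=f"g{group_id:03d}/N{i}")
        for i in range(cfg.normals_per_group)
    )
    return ModelGroup(tumors, normals, cfg.n_targets)


def generate_benchmark(cfg: GeneratorConfig) -> list[ModelGroup]:
    """Draw ``n_groups`` groups, each from its own spawned RNG substream."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_groups)
    return [
        generate_group(cfg, np.random.default_rng(child), group_id=i)
        for i, child in enumerate(children)
    ]
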