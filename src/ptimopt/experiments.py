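"""Benchmark harness: per-group optimization, nTumor x nNormal tables, sweeps.

A benchmark cell fixes how many tumor and normal models of each group take
part (the deterministic leading prefix of each group, so nested cells are
comparable), runs the configured search per group, and averages the best
feasible tumor objective and the evaluation count over groups.  A table
iterates the full nTumor x nNormal grid; a sweep re-runs the (5, 5) cell
while varying one algorithm parameter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gact import GactParams, gact_search
from .hillclimb import HcParams, hc_search
from .lexsearch import exhaustive_search, lex_search, lex_search_prefixes
from .models import ModelGroup
from .objectives import ObjectiveSpec
from .synthetic import GeneratorConfig, generate_benchmark

__all__ = ["ExperimentConfig", "CellResult", "TableResult", "run_cell", "run_table", "sweep"]

ALGORITHMS = ("lex", "exhaustive", "gact", "hc")


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    algorithm: str = "lex"
    mode: str = "wco"
    theta: float = 0.1
    gact: GactParams = field(default_factory=GactParams)
    hc: HcParams = field(default_factory=HcParams)
    seed: int = 0  # seeds the stochastic search algorithms (generator has its own)
    n_tumor_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_normal_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    verbosity: int = 0
    log_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        g = self.generator
        if max(self.n_tumor_grid) > g.tumors_per_group or max(self.n_normal_grid) > g.normals_per_group:
            raise ValueError("grid exceeds per-group model counts")

    @property
    def spec(self) -> ObjectiveSpec:
        return ObjectiveSpec(self.mode, self.theta)


@dataclass(frozen=True)
class CellResult:
    mean_value: float
    mean_evaluations: float
    n_groups: int


@dataclass(frozen=True)
class TableResult:
    values: pd.DataFrame  # rows nTumor, columns nNormal
    evaluations: pd.DataFrame


def _run_one(cfg: ExperimentConfig, group: ModelGroup, group_id: int):
    spec = cfg.spec
    if cfg.algorithm == "lex":
        return lex_search(group, spec)
    if cfg.algorithm == "exhaustive":
        return exhaustive_search(group, spec)
    rng = np.random.default_rng([cfg.seed, group_id])
    if cfg.algorithm == "gact":
        return gact_search(group, spec, cfg.gact, rng)
    return hc_search(group, spec, cfg.hc, rng)


def _log(cfg: ExperimentConfig, fh, group_id: int, n_tumor: int, n_normal: int, res) -> None:
    if fh is None:
        return
    fh.write(json.dumps({
        "group": group_id,
        "algo": cfg.algorithm,
        "mode": cfg.mode,
        "n_tumor": n_tumor,
        "n_normal": n_normal,
        "best_phi": res.best_phi.to_string(),
        "best_value": res.best_value,
        "evaluations": res.evaluations,
        "feasible_found": res.feasible_found,
    }) + "\n")


def run_cell(
    cfg: ExperimentConfig,
    n_tumor: int,
    n_normal: int,
    groups: Optional[Sequence[ModelGroup]] = None,
) -> CellResult:
    """Mean best feasible value and evaluation count over all groups.

    Each group contributes its first ``n_tumor`` tumor and first ``n_normal``
    normal models; a group with no feasible nonempty therapy contributes the
    empty therapy's value 0.
    """
    groups = generate_benchmark(cfg.generator) if groups is None else groups
    fh = open(cfg.log_path, "a") if (cfg.log_path and cfg.verbosity >= 1) else None
    try:
        values, evals = [], []
        for i, g in enumerate(groups):
            res = _run_one(cfg, g.subselect(n_tumor, n_normal), i)
            _log(cfg, fh, i, n_tumor, n_normal, res)
            values.append(res.best_value)
            evals.append(res.evaluations)
    finally:
        if fh:
            fh.close()
    return CellResult(float(np.mean(values)), float(np.mean(evals)), len(groups))


def _lex_table(cfg: ExperimentConfig, groups: Sequence[ModelGroup]):
    """Shared-traversal table for the exact search.

    For a fixed normal prefix, pruning is identical across tumor prefixes, so
    one traversal per (group, nNormal) scores every nTumor cell; results
    equal per-cell ``lex_search`` runs exactly.
    """
    nT, nN = cfg.n_tumor_grid, cfg.n_normal_grid
    vals = np.zeros((len(nT), len(nN)))
    evs = np.zeros((len(nT), len(nN)))
    for g in groups:
        for j, n_normal in enumerate(nN):
            sub = ModelGroup(g.tumors, g.normals[:n_normal], g.n_targets)
            results = lex_search_prefixes(sub, cfg.spec, nT)
            for i, res in enumerate(results):
                vals[i, j] += res.best_value
                evs[i, j] += res.evaluations
    return vals / len(groups), evs / len(groups)


def run_table(
    cfg: ExperimentConfig,
    groups: Optional[Sequence[ModelGroup]] = None,
    csv_path: Optional[str] = None,
) -> TableResult:
    """The nTumor x nNormal benchmark table (rows nTumor, columns nNormal)."""
    groups = generate_benchmark(cfg.generator) if groups is None else groups
    nT, nN = cfg.n_tumor_grid, cfg.n_normal_grid
    if cfg.algorithm == "lex":
        vals, evs = _lex_table(cfg, groups)
    else:
        vals = np.zeros((len(nT), len(nN)))
        evs = np.zeros((len(nT), len(nN)))
        for i, n_tumor in enumerate(nT):
            for j, n_normal in enumerate(nN):
                cell = run_cell(cfg, n_tumor, n_normal, groups)
                vals[i, j], evs[i, j] = cell.mean_value, cell.mean_evaluations
    values = pd.DataFrame(vals, index=pd.Index(nT, name="nTumor"),
                          columns=pd.Index(nN, name="nNormal"))
    evaluations = pd.DataFrame(evs, index=values.index, columns=values.columns)
    if csv_path:
        values.to_csv(csv_path, float_format="%.6f")
    return TableResult(values, evaluations)


def _replace_param(cfg: ExperimentConfig, parameter: str, value) -> ExperimentConfig:
    """Return a config with a (possibly dotted, e.g. ``gact.rate_m``) field set."""
    if "." in parameter:
        head, tail = parameter.split(".", 1)
        inner = dataclasses.replace(getattr(cfg, head), **{tail: value})
        return dataclasses.replace(cfg, **{head: inner})
    return dataclasses.replace(cfg, **{parameter: value})


def sweep(
    cfg: ExperimentConfig,
    parameter: str,
    values: Sequence,
    n_tumor: int = 5,
    n_normal: int = 5,
    groups: Optional[Sequence[ModelGroup]] = None,
) -> pd.DataFrame:
    """Re-run one cell while varying a single parameter; one row per value."""
    groups = generate_benchmark(cfg.generator) if groups is None else groups
    rows = []
    for v in values:
        cell = run_cell(_replace_param(cfg, parameter, v), n_tumor, n_normal, groups)
        rows.append({parameter: v, "mean_value": cell.mean_value,
                     "mean_evaluations": cell.mean_evaluations})
    return pd.DataFrame(rows)
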