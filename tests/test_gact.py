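"""Pareto dominance, genetic operators and the GACT search."""

import numpy as np
import pytest

from ptimopt import (
    GactParams,
    GeneratorConfig,
    ObjectiveSpec,
    ParetoPoint,
    TargetSet,
    crossover,
    dominates,
    gact_search,
    generate_group,
    lex_search,
    mutate,
)
from ptimopt.models import Block, CircuitModel, LookupPTIM, ModelGroup
from ptimopt.gact import pareto_front, _front_layers


def _pt(tumor, tox):
    return ParetoPoint(TargetSet.from_string("0"), tumor, tox)


class TestDominance:
    def test_better_tumor_same_tox_dominates(self):
        assert dominates(_pt(0.8, 0.05), _pt(0.7, 0.05))

    def test_equal_points_do_not_dominate(self):
        assert not dominates(_pt(0.8, 0.05), _pt(0.8, 0.05))

    def test_trade_off_is_incomparable(self):
        a, b = _pt(0.9, 0.2), _pt(0.7, 0.05)
        assert not dominates(a, b) and not dominates(b, a)


class TestParetoFront:
    def test_dominated_point_removed(self):
        pts = [_pt(0.8, 0.05), _pt(0.7, 0.05), _pt(0.9, 0.2)]
        front = pareto_front(pts)
        assert front == [pts[0], pts[2]]

    def test_single_point_is_its_own_front(self):
        pts = [_pt(0.5, 0.5)]
        assert pareto_front(pts) == pts

    def test_duplicates_all_retained(self):
        pts = [_pt(0.5, 0.1), _pt(0.5, 0.1)]
        assert pareto_front(pts) == pts

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(0)
        pts = [_pt(t, x) for t, x in rng.random((40, 2))]
        brute = [
            p for p in pts if not any(dominates(q, p) for q in pts if q is not p)
        ]
        assert pareto_front(pts) == brute

    def test_layer_peeling_matches_repeated_fronts(self):
        rng = np.random.default_rng(3)
        tumor, tox = rng.random(30), rng.random(30)
        layers = _front_layers(tumor, tox, need=30)
        pts = [_pt(t, x) for t, x in zip(tumor, tox)]
        remaining = list(range(30))
        expected = np.empty(30, int)
        level = 0
        while remaining:
            sub = [pts[i] for i in remaining]
            front = pareto_front(sub)
            keep = [i for i, p in zip(remaining, sub) if p in front]
            for i in keep:
                expected[i] = level
            remaining = [i for i in remaining if i not in keep]
            level += 1
        assert (layers == expected).all()


class TestOperators:
    def test_crossover_of_identical_parents_is_identity(self):
        a = TargetSet.from_string("10101")
        assert crossover(a, a, np.random.default_rng(0)) == a

    def test_crossover_mixes_each_position_evenly(self):
        rng = np.random.default_rng(1)
        a, b = TargetSet.from_string("111"), TargetSet.from_string("000")
        freq = np.mean(
            [crossover(a, b, rng).bits for _ in range(4000)], axis=0
        )
        assert np.all(np.abs(freq - 0.5) < 0.03)

    def test_crossover_positionwise_pick_pattern(self):
        # with picks (a1, b2, a3): a=[1,0,1], b=[0,1,0] -> [1,1,1]
        a, b = TargetSet((1, 0, 1)), TargetSet((0, 1, 0))
        seen = {
            crossover(a, b, np.random.default_rng(s)).bits for s in range(200)
        }
        assert (1, 1, 1) in seen  # the (a1, b2, a3) pick occurs
        assert seen <= {(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)}

    def test_crossover_length_mismatch(self):
        with pytest.raises(ValueError):
            crossover(TargetSet((1,)), TargetSet((1, 0)), np.random.default_rng(0))

    def test_mutation_rate_extremes(self):
        a = TargetSet.from_string("1010")
        rng = np.random.default_rng(0)
        assert mutate(a, 0.0, rng) == a
        assert mutate(a, 1.0, rng) == TargetSet.from_string("0101")

    def test_mutation_mean_hamming_distance(self):
        rng = np.random.default_rng(2)
        a = TargetSet((0,) * 20)
        dist = np.mean([sum(mutate(a, 0.2, rng).bits) for _ in range(4000)])
        assert dist == pytest.approx(0.2 * 20, rel=0.05)


class TestGactSearch:
    def test_finds_known_optimum_on_tiny_instance(self):
        tumor = CircuitModel(3, (Block(frozenset({0}), 0.9),), kind="tumor")
        normal = LookupPTIM(3, {m: 0.0 for m in range(8)}, kind="normal")
        g = ModelGroup((tumor,), (normal,), 3)
        params = GactParams(pop_size=20, total_generations=50, off_min=50, off_max=5000)
        res = gact_search(g, ObjectiveSpec("wco", 0.1), params, np.random.default_rng(0))
        assert res.feasible_found and res.best_value == pytest.approx(0.9)

    def test_deterministic_under_seed(self):
        g = generate_group(GeneratorConfig(n_targets=8, n_groups=1), np.random.default_rng(4))
        spec = ObjectiveSpec("wco", 0.1)
        a = gact_search(g, spec, GactParams(), np.random.default_rng(9))
        b = gact_search(g, spec, GactParams(), np.random.default_rng(9))
        assert a == b

    def test_never_beats_exact_search_and_history_never_degrades(self):
        spec = ObjectiveSpec("wco", 0.1)
        for seed in range(8):
            cfg = GeneratorConfig(n_targets=10, n_groups=1, seed=seed)
            g = generate_group(cfg, np.random.default_rng(seed))
            exact = lex_search(g, spec)
            res = gact_search(
                g, spec, GactParams(), np.random.default_rng(seed), record_history=True
            )
            assert res.best_value <= exact.best_value + 1e-12
            finite = [h for h in res.history if h > -np.inf]
            assert all(b >= a - 1e-12 for a, b in zip(finite, finite[1:]))

    def test_infeasible_everything_returns_empty_fallback(self):
        tum = LookupPTIM(2, {m: 1.0 for m in range(4)}, kind="tumor")
        norm = LookupPTIM(2, {m: 0.9 for m in range(4)}, kind="normal")
        g = ModelGroup((tum,), (norm,), 2)
        res = gact_search(g, ObjectiveSpec("wco", 0.1),
                          GactParams(pop_size=10, total_generations=3, off_min=20),
                          np.random.default_rng(0))
        assert not res.feasible_found and res.best_value == 0.0
        assert res.best_phi == TargetSet.empty(2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GactParams(rate_m=1.5)
        with pytest.raises(ValueError):
            GactParams(off_min=100, off_max=10)
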