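"""Circuit and lookup PTIM evaluation, bit-vector algebra and model I/O."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptimopt import (
    Block,
    CircuitModel,
    LookupPTIM,
    ModelFormatError,
    ModelGroup,
    MonotonicityWarning,
    TargetSet,
    block_inhibition,
    circuit_sensitivity,
    lookup_sensitivity,
    read_lookup_tsv,
    read_models,
    tabulate_circuit,
    write_lookup_tsv,
    write_models,
)
from ptimopt.synthetic import GeneratorConfig, generate_group


class TestTargetSet:
    def test_string_convention_maps_leading_position_to_target_zero(self):
        phi = TargetSet.from_string("1100")
        assert phi.indices == (0, 1)
        assert phi.mask == 0b0011
        assert phi.to_string() == "1100"
        assert TargetSet.from_mask(phi.mask, 4) == phi

    def test_subset_and_union(self):
        a = TargetSet.from_string("100")
        b = TargetSet.from_string("101")
        assert a.issubset(b) and not b.issubset(a)
        assert a.union(TargetSet.from_string("001")) == b

    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError):
            TargetSet((0, 2, 1))


@pytest.mark.parametrize(
    "members, phi, expected",
    [
        ({0, 1}, "110", 1),  # all members inhibited
        ({0, 1}, "100", 0),  # min of {1, 0}
        ({2}, "001", 1),  # singleton block
    ],
)
def test_block_inhibition(members, phi, expected):
    block = Block(frozenset(members), 0.9)
    assert block_inhibition(block, TargetSet.from_string(phi)) == expected


def test_block_inhibition_rejects_out_of_range_member():
    with pytest.raises(IndexError):
        block_inhibition(Block(frozenset({5}), 0.5), TargetSet.from_string("001"))


class TestCircuitSensitivity:
    @pytest.mark.parametrize(
        "phi, expected",
        [
            ("001", 0.75),  # singleton block alone
            ("110", 0.95),  # parallel block alone
            ("000", 0.0),  # no block inhibited
            ("111", 1 - (1 - 0.95) * (1 - 0.75)),  # both blocks: 0.9875
        ],
    )
    def test_example_circuit(self, example_circuit, phi, expected):
        got = circuit_sensitivity(example_circuit, TargetSet.from_string(phi))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_raises(self, example_circuit):
        with pytest.raises(ValueError):
            circuit_sensitivity(example_circuit, TargetSet.from_string("01"))

    def test_empty_blocks_rejected(self):
        with pytest.raises(ModelFormatError):
            CircuitModel(3, ())


@given(seed=st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_circuit_monotone_under_inclusion(seed):
    """Adding inhibitions never decreases a circuit's sensitivity."""
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(n_targets=8, n_blocks=3, max_block_size=3, n_groups=1)
    model = generate_group(cfg, rng).tumors[0]
    small = rng.integers(0, 2, 8)
    extra = rng.integers(0, 2, 8)
    phi1 = TargetSet(tuple(small))
    phi2 = TargetSet(tuple(small | extra))
    s1, s2 = circuit_sensitivity(model, phi1), circuit_sensitivity(model, phi2)
    assert 0.0 <= s1 <= s2 <= 1.0


def test_tabulated_circuit_matches_direct_evaluation(example_circuit):
    lut = tabulate_circuit(example_circuit)
    assert lut.complete and not lut.monotonicity_violations()
    for mask in range(8):
        phi = TargetSet.from_mask(mask, 3)
        assert lookup_sensitivity(lut, phi) == circuit_sensitivity(example_circuit, phi)


class TestLookup:
    def test_stored_value_returned(self):
        lut = LookupPTIM(1, {0: 0.0, 1: 0.4})
        assert lookup_sensitivity(lut, TargetSet.from_string("0")) == 0.0

    def test_partial_table_missing_key_raises(self):
        lut = LookupPTIM(2, {0: 0.0})
        assert not lut.complete
        with pytest.raises(KeyError):
            lookup_sensitivity(lut, TargetSet.from_string("01"))


class TestIO:
    def test_circuit_json_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        group = generate_group(GeneratorConfig(n_groups=1), rng)
        path = tmp_path / "models.json"
        write_models(group, path)
        back = read_models(path)
        assert back == group
        write_models(back, tmp_path / "again.json")
        assert (tmp_path / "again.json").read_text() == path.read_text()

    def test_lookup_tsv_round_trip(self, tmp_path, example_circuit):
        lut = tabulate_circuit(example_circuit)
        path = tmp_path / "lut.tsv"
        write_lookup_tsv(lut, path)
        back = read_lookup_tsv(path)
        assert back.n_targets == 3
        assert back.table == pytest.approx(lut.table)

    def test_monotonicity_violation_warns_on_load(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "targets\tsensitivity\n000\t0\n001\t0.75\n110\t0\n111\t0.5\n"
        )
        with pytest.warns(MonotonicityWarning, match="001"):
            read_lookup_tsv(path)

    def test_malformed_json_reports_context(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"n_targets": 3, "models": [{"blocks": []}]}')
        with pytest.raises(ModelFormatError, match="models"):
            read_models(path)
        path.write_text("not json")
        with pytest.raises(ModelFormatError, match="line"):
            read_models(path)

    def test_group_requires_both_kinds(self, tmp_path):
        path = tmp_path / "t.json"
        payload = {
            "n_targets": 2,
            "models": [{"label": "", "kind": "tumor",
                        "blocks": [{"members": [0], "score": 0.5}]}],
        }
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError, match="normal"):
            read_models(path)


def test_group_invariants():
    t = CircuitModel(2, (Block(frozenset({0}), 0.5),), kind="tumor")
    n = CircuitModel(2, (Block(frozenset({1}), 0.5),), kind="normal")
    g = ModelGroup((t,), (n,), 2)
    assert (g.k, g.p, g.n_targets) == (1, 1, 2)
    with pytest.raises(ValueError):
        ModelGroup((t,), (), 2)
    bad = CircuitModel(3, (Block(frozenset({0}), 0.5),), kind="normal")
    with pytest.raises(ValueError):
        ModelGroup((t,), (bad,))
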