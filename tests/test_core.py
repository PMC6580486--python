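"""Sensitivity scaling, binarization, block scoring, search, and circuits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptim.core import (
    InhibitionMatrix,
    PtimBlock,
    assemble_circuit,
    binarize_targets,
    brute_force_fit,
    circuit_to_dot,
    circuit_to_json,
    inverse_scale_sensitivity,
    model_objective,
    scale_sensitivity,
    score_block,
    search_blocks,
)
from ptim.integration import TargetPriorSet
from ptim.screens import Drug, TargetProfile, ValidationError


class TestScaleSensitivity:
    def test_at_or_below_cmax_is_one(self):
        assert scale_sensitivity(10.0, 10_000.0, cmax=10.0) == 1.0
        assert scale_sensitivity(5.0, 10_000.0, cmax=10.0) == 1.0

    def test_at_max_dose_is_zero(self):
        assert scale_sensitivity(10_000.0, 10_000.0, cmax=10.0) == 0.0

    def test_printed_formula_midpoint(self):
        # max 10^4 nM, ic50 10^2 nM: (4 - 2) / 4 = 0.5
        assert scale_sensitivity(100.0, 10_000.0, cmax=10.0) == pytest.approx(0.5)

    def test_without_cmax_only_log_branch(self):
        assert scale_sensitivity(1.0, 10_000.0) == pytest.approx(1.0)
        assert scale_sensitivity(100.0, 10_000.0) == pytest.approx(0.5)

    def test_above_max_clamps_to_zero(self):
        assert scale_sensitivity(1e6, 10_000.0, cmax=10.0) == 0.0

    def test_low_max_dose_rejected(self):
        with pytest.raises(ValidationError):
            scale_sensitivity(0.5, 1.0)

    @given(
        ic50s=st.lists(st.floats(0.1, 1e7), min_size=2, max_size=2),
        cmax=st.one_of(st.none(), st.floats(1.0, 1e4)),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_non_increasing(self, ic50s, cmax):
        lo, hi = sorted(ic50s)
        assert scale_sensitivity(lo, 1e5, cmax) >= scale_sensitivity(hi, 1e5, cmax)

    @given(y=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_round_trip(self, y):
        ic50 = inverse_scale_sensitivity(y, 10_000.0)
        assert scale_sensitivity(ic50, 10_000.0) == pytest.approx(y, abs=1e-12)


class TestBinarize:
    def test_cmax_rule_with_boundary(self):
        drugs = {"d": Drug("d", "n", max_tested_dose=1e4, cmax=1000.0)}
        profiles = [TargetProfile("d", "A", 1000.0), TargetProfile("d", "B", 20_000.0)]
        m = binarize_targets(profiles, drugs)
        assert m.inhibited("d") == frozenset({"A"})

    def test_missing_pair_is_zero(self):
        drugs = {"d": Drug("d", "n", max_tested_dose=1e4, cmax=100.0),
                 "e": Drug("e", "n", max_tested_dose=1e4, cmax=100.0)}
        m = binarize_targets([TargetProfile("d", "A", 50.0)], drugs)
        assert m.inhibited("e") == frozenset()

    def test_fallback_to_max_dose_without_cmax(self):
        drugs = {"d": Drug("d", "n", max_tested_dose=1e4)}
        m = binarize_targets([TargetProfile("d", "A", 5000.0)], drugs)
        assert m.inhibited("d") == frozenset({"A"})

    def test_absolute_rule(self):
        drugs = {"d": Drug("d", "n", max_tested_dose=1e4, cmax=1e4)}
        profiles = [TargetProfile("d", "A", 50.0), TargetProfile("d", "B", 500.0)]
        m = binarize_targets(profiles, drugs, rule="absolute", threshold=100.0)
        assert m.inhibited("d") == frozenset({"A"})


def _matrix(rows, targets):
    frame = pd.DataFrame(rows, columns=targets)
    frame.index = [f"d{i}" for i in range(len(rows))]
    return InhibitionMatrix(frame)


class TestScoreBlock:
    def test_shrunk_mean_default(self):
        m = _matrix([[1], [1], [1]], ["A"])
        y = {"d0": 1.0, "d1": 1.0, "d2": 1.0}
        block = score_block({"A"}, m, y)
        assert block.score == pytest.approx(0.75)  # (3 + 0) / (3 + 1)

    def test_alpha_zero_is_mean(self):
        m = _matrix([[1], [1]], ["A"])
        y = {"d0": 0.4, "d1": 0.6}
        assert score_block({"A"}, m, y, alpha=0.0).score == pytest.approx(0.5)

    def test_zero_sensitivity_supporters(self):
        m = _matrix([[1], [1]], ["A"])
        assert score_block({"A"}, m, {"d0": 0.0, "d1": 0.0}).score == 0.0

    def test_unsupported_block_not_emitted(self):
        m = _matrix([[1, 0], [0, 1]], ["A", "B"])
        assert score_block({"A", "B"}, m, {"d0": 1.0, "d1": 1.0}) is None


class TestSearch:
    def test_planted_single_target(self):
        # drugs hitting A are sensitive (0.9), the rest are near-dead
        rows = [[1, 0, 0]] * 5 + [[0, 1, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0], [0, 0, 1]]
        m = _matrix(rows, ["A", "B", "C"])
        y = {f"d{i}": (0.9 if i < 5 else 0.05) for i in range(10)}
        blocks, _ = search_blocks(m, y, mode="exhaustive", max_blocks=3)
        best = max(blocks, key=lambda b: b.score)
        assert best.targets == frozenset({"A"})
        assert best.score == pytest.approx(0.9 * 5 / 6)

    def test_planted_parallel_pair(self):
        # only drugs hitting BOTH C and D are sensitive
        rows = [[1, 1, 0], [1, 1, 0], [1, 1, 1], [1, 0, 0], [0, 1, 0], [1, 0, 1], [0, 1, 1]]
        m = _matrix(rows, ["C", "D", "E"])
        y = {f"d{i}": (0.8 if rows[i][0] and rows[i][1] else 0.0) for i in range(7)}
        blocks, sse = search_blocks(m, y, mode="exhaustive", max_blocks=2, alpha=0.0)
        assert frozenset({"C", "D"}) in {b.targets for b in blocks}
        singles = [b for b in blocks if len(b.targets) == 1]
        assert all(b.score < 0.8 for b in singles)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_all_insensitive_yields_no_blocks(self):
        m = _matrix([[1, 0], [0, 1]], ["A", "B"])
        blocks, sse = search_blocks(m, {"d0": 0.0, "d1": 0.0}, mode="exhaustive")
        assert blocks == []
        assert sse == 0.0

    def test_empty_candidate_set_errors(self):
        m = _matrix([[1]], ["A"])
        priors = TargetPriorSet(["A"])
        priors.set("A", "excluded", "test")
        with pytest.raises(ValidationError):
            search_blocks(m, {"d0": 1.0}, priors=priors)

    def test_excluded_targets_never_in_blocks(self):
        rows = [[1, 1], [1, 1], [1, 0], [0, 1]]
        m = _matrix(rows, ["A", "B"])
        y = {"d0": 0.9, "d1": 0.9, "d2": 0.8, "d3": 0.1}
        priors = TargetPriorSet(["A", "B"])
        priors.set("B", "excluded", "test")
        blocks, _ = search_blocks(m, y, priors=priors, mode="exhaustive")
        assert all("B" not in b.targets for b in blocks)

    def test_required_target_forced_into_model(self):
        rows = [[1, 0], [1, 0], [1, 0], [0, 1]]
        m = _matrix(rows, ["A", "B"])
        y = {"d0": 0.9, "d1": 0.9, "d2": 0.9, "d3": 0.0}
        priors = TargetPriorSet(["A", "B"])
        priors.set("B", "required", "test")
        blocks, _ = search_blocks(m, y, priors=priors, mode="exhaustive")
        assert any("B" in b.targets for b in blocks)

    def test_beam_matches_exhaustive_on_small_instance(self):
        rng = np.random.default_rng(5)
        rows = (rng.uniform(size=(15, 6)) < 0.4).astype(int)
        m = _matrix(rows.tolist(), list("ABCDEF"))
        y = {f"d{i}": float(rng.uniform()) for i in range(15)}
        _, sse_ex = search_blocks(m, y, mode="exhaustive", max_blocks=3, max_block_size=3)
        _, sse_beam = search_blocks(
            m, y, mode="beam", max_blocks=3, max_block_size=3, min_gain_frac=0.0
        )
        assert sse_beam >= sse_ex - 1e-12  # beam is a heuristic lower-bounded by optimum


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        nt = int(rng.integers(4, 8))
        rows = (rng.uniform(size=(20, nt)) < 0.4).astype(int)
        m = _matrix(rows.tolist(), [f"T{j}" for j in range(nt)])
        y = {f"d{i}": float(rng.uniform()) for i in range(20)}
        _, sse = search_blocks(m, y, mode="exhaustive", max_blocks=3, max_block_size=3)
        _, oracle_sse = brute_force_fit(m, y, max_blocks=3, max_block_size=3)
        assert sse == pytest.approx(oracle_sse, abs=1e-9)

    def test_single_target_instance_trivial(self):
        m = _matrix([[1], [1], [0]], ["A"])
        y = {"d0": 0.6, "d1": 0.6, "d2": 0.0}
        blocks, sse = brute_force_fit(m, y, alpha=0.0)
        assert blocks[0].targets == frozenset({"A"})
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_refuses_large_instance(self):
        m = _matrix([[1] * 13], [f"T{j}" for j in range(13)])
        with pytest.raises(ValidationError):
            brute_force_fit(m, {"d0": 1.0})


class TestPredictionMonotonicity:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_adding_inhibited_target_never_decreases_prediction(self, seed):
        rng = np.random.default_rng(seed)
        rows = (rng.uniform(size=(12, 5)) < 0.5).astype(int)
        m = _matrix(rows.tolist(), list("ABCDE"))
        y = {f"d{i}": float(rng.uniform()) for i in range(12)}
        blocks, _ = search_blocks(m, y, mode="beam", max_blocks=3)
        circuit = assemble_circuit(blocks)
        inhibited = set(rng.choice(list("ABCDE"), size=2, replace=False))
        extra = inhibited | {rng.choice(list("ABCDE"))}
        assert circuit.predict(extra) >= circuit.predict(inhibited)


class TestAssembleCircuit:
    def _block(self, targets, score):
        return PtimBlock(frozenset(targets), score, frozenset({"d0"}))

    def test_descending_score_order(self):
        blocks = [
            self._block({"D"}, 0.750),
            self._block({"A"}, 0.825),
            self._block({"C"}, 0.775),
            self._block({"B"}, 0.800),
        ]
        circuit = assemble_circuit(blocks)
        assert [b.score for b in circuit.blocks] == [0.825, 0.800, 0.775, 0.750]

    def test_equal_score_lexicographic_tie_break(self):
        circuit = assemble_circuit(
            [self._block({"B", "A"}, 0.7), self._block({"A", "C"}, 0.7)]
        )
        assert circuit.blocks[0].sorted_targets == ("A", "B")

    def test_lower_scoring_superset_kept(self):
        a = self._block({"A"}, 0.9)
        ab = self._block({"A", "B"}, 0.6)
        circuit = assemble_circuit([a, ab])
        assert {b.targets for b in circuit.blocks} == {a.targets, ab.targets}

    def test_subset_of_stronger_block_dropped(self):
        a = self._block({"A"}, 0.6)
        ab = self._block({"A", "B"}, 0.9)
        circuit = assemble_circuit([a, ab])
        assert {b.targets for b in circuit.blocks} == {ab.targets}

    def test_required_target_enforced(self):
        priors = TargetPriorSet(["A", "Z"])
        priors.set("Z", "required", "test")
        with pytest.raises(ValidationError, match="required"):
            assemble_circuit([self._block({"A"}, 0.5)], priors=priors)

    def test_objective_recomputes(self):
        m = _matrix([[1, 0], [1, 1], [0, 1]], ["A", "B"])
        y = {"d0": 0.6, "d1": 0.6, "d2": 0.1}
        blocks, sse = search_blocks(m, y, mode="exhaustive", max_blocks=2)
        assert model_objective(blocks, m, y) == pytest.approx(sse)

    def test_exports(self):
        circuit = assemble_circuit(
            [self._block({"A"}, 0.9), self._block({"B", "C"}, 0.6)]
        )
        payload = circuit_to_json(circuit)
        assert '"targets"' in payload and '"A"' in payload
        dot = circuit_to_dot(circuit)
        assert dot.startswith("digraph") and "B|C" in dot
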