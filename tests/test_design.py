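"""Combination-plan design: coverage, ranking, consensus, resistance, dosing."""

import pytest

from ptim.core import PtimBlock, PtimCircuit
from ptim.design import (
    Formulary,
    cover_block,
    design_consensus,
    design_resistance_abrogation,
    design_synergy,
)
from ptim.screens import Drug, TargetProfile, ValidationError


def _block(targets, score, supporters=("s1",)):
    return PtimBlock(frozenset(targets), score, frozenset(supporters))


def _formulary(layout, cmax=2000.0):
    """layout: {drug_id: {target: ec50}}"""
    drugs = {
        d: Drug(d, d, max_tested_dose=20_000.0, cmax=cmax) for d in layout
    }
    profiles = [
        TargetProfile(d, t, ec50) for d, targets in layout.items()
        for t, ec50 in targets.items()
    ]
    return Formulary(drugs=drugs, profiles=profiles)


class TestCoverBlock:
    def test_igf1r_pik3ca_style_pairing(self):
        # dual IGF1R/INSR inhibitor + PI3K inhibitor jointly cover the block
        formulary = _formulary(
            {
                "OSI-906": {"Igf1r": 10.0, "Insr": 30.0},
                "GDC-0941": {"Pik3ca": 50.0},
                "sorafenib": {"Kdr": 90.0},
            }
        )
        block = _block({"Igf1r", "Pik3ca"}, 0.9)
        covers = cover_block(block, formulary)
        assert covers == [frozenset({"OSI-906", "GDC-0941"})]

    def test_single_target_single_inhibitor(self):
        formulary = _formulary({"x": {"A": 10.0}, "y": {"B": 10.0}})
        assert cover_block(_block({"A"}, 0.5), formulary) == [frozenset({"x"})]

    def test_uncoverable_block_empty(self):
        formulary = _formulary({"x": {"A": 10.0}, "y": {"B": 10.0}})
        assert cover_block(_block({"A", "B", "C", "D"}, 0.5), formulary) == []

    def test_pairs_containing_covering_singleton_not_minimal(self):
        formulary = _formulary({"both": {"A": 10.0, "B": 10.0}, "x": {"A": 5.0}})
        covers = cover_block(_block({"A", "B"}, 0.5), formulary)
        assert covers == [frozenset({"both"})]

    def test_tighter_inhibition_ranked_first(self):
        formulary = _formulary(
            {
                "loose": {"A": 1500.0, "B": 1500.0},
                "t1": {"A": 20.0},
                "t2": {"B": 30.0},
            }
        )
        covers = cover_block(_block({"A", "B"}, 0.5), formulary)
        assert covers[0] == frozenset({"t1", "t2"})


class TestSynergy:
    def test_top_block_pair_ranked_first(self):
        circuit = PtimCircuit(
            [_block({"Igf1r", "Pik3ca"}, 0.9), _block({"Kdr", "Axl"}, 0.7)]
        )
        formulary = _formulary(
            {
                "OSI-906": {"Igf1r": 10.0, "Insr": 30.0},
                "GDC-0941": {"Pik3ca": 50.0},
                "sunitinib": {"Kdr": 20.0, "Axl": 80.0},
            }
        )
        plans = design_synergy(circuit, formulary)
        assert plans[0].drugs == frozenset({"GDC-0941", "OSI-906"})
        assert plans[0].plan_score == pytest.approx(0.9)
        assert plans[1].drugs == frozenset({"sunitinib"})

    def test_single_target_only_circuit_has_no_synergy_plans(self):
        circuit = PtimCircuit([_block({"A"}, 0.9)])
        formulary = _formulary({"x": {"A": 10.0}})
        assert design_synergy(circuit, formulary) == []

    def test_higher_scoring_block_wins_ranking(self):
        circuit = PtimCircuit([_block({"A", "B"}, 0.9), _block({"C", "D"}, 0.7)])
        formulary = _formulary(
            {"ab": {"A": 10.0, "B": 10.0}, "cd": {"C": 10.0, "D": 10.0}}
        )
        plans = design_synergy(circuit, formulary)
        assert [p.plan_score for p in plans] == [pytest.approx(0.9), pytest.approx(0.7)]

    def test_formulary_monotonicity(self):
        circuit = PtimCircuit([_block({"A", "B"}, 0.8)])
        small = _formulary({"a": {"A": 10.0}, "b": {"B": 10.0}})
        plans_small = {p.drugs for p in design_synergy(circuit, small)}
        big = _formulary(
            {"a": {"A": 10.0}, "b": {"B": 10.0}, "c": {"A": 5.0, "B": 5.0}}
        )
        plans_big = {p.drugs for p in design_synergy(circuit, big)}
        assert plans_small <= plans_big


class TestConsensus:
    def _sites(self):
        return {
            "site1": PtimCircuit([_block({"Kdr", "Pik3ca"}, 0.8), _block({"X"}, 0.9)]),
            "site2": PtimCircuit([_block({"Kdr", "Mtor"}, 0.7)]),
            "site3": PtimCircuit([_block({"Pik3ca", "Mtor"}, 0.6)]),
        }

    def _formulary(self):
        return _formulary(
            {
                "sunitinib": {"Kdr": 20.0, "Axl": 50.0},
                "BEZ235": {"Pik3ca": 30.0, "Mtor": 40.0},
                "other": {"X": 10.0},
            }
        )

    def test_shared_pair_found_across_all_sites(self):
        plans, diags = design_consensus(self._sites(), self._formulary())
        assert plans, "expected a consensus plan"
        top = plans[0]
        assert top.drugs == frozenset({"BEZ235", "sunitinib"})
        assert set(top.covered_blocks) == {"site1", "site2", "site3"}
        # min-aggregation: weakest site (0.6) bounds the plan score
        assert top.plan_score == pytest.approx(0.6)
        assert all(diags.values())

    def test_min_aggregation_bounds_per_site_score(self):
        plans, _ = design_consensus(self._sites(), self._formulary())
        for plan in plans:
            for blocks in plan.covered_blocks.values():
                assert plan.plan_score <= max(b.score for b in blocks) + 1e-12

    def test_identical_circuits_match_single_model_ranking(self):
        circuit = PtimCircuit([_block({"Kdr", "Pik3ca"}, 0.8)])
        formulary = self._formulary()
        plans, _ = design_consensus({"a": circuit, "b": circuit}, formulary)
        synergy = design_synergy(circuit, formulary)
        assert plans[0].drugs == synergy[0].drugs
        assert plans[0].plan_score == pytest.approx(synergy[0].plan_score)

    def test_uncoverable_site_named_in_diagnostics(self):
        sites = self._sites()
        sites["site4"] = PtimCircuit([_block({"Zzz"}, 0.9)])
        plans, diags = design_consensus(sites, self._formulary())
        assert plans == []
        assert diags["site4"] is False
        assert diags["site1"] is True

    def test_needs_two_circuits(self):
        with pytest.raises(ValidationError):
            design_consensus({"one": PtimCircuit([])}, self._formulary())


class TestResistance:
    def _formulary(self, cmax=2000.0):
        return _formulary(
            {
                "panobinostat": {"Hdac7": 100.0},
                "obatoclax": {"Mcl1": 200.0},
                "wide": {"Hdac7": 400.0, "Mcl1": 900.0},
            },
            cmax=cmax,
        )

    def test_two_disjoint_single_blocks(self):
        circuit = PtimCircuit([_block({"Hdac7"}, 0.8), _block({"Mcl1"}, 0.7)])
        plans = design_resistance_abrogation(circuit, self._formulary())
        assert plans
        assert plans[0].drugs == frozenset({"obatoclax", "panobinostat"})
        assert plans[0].plan_score == pytest.approx(0.7)

    def test_dose_is_1_5x_ec50_when_below_cmax(self):
        circuit = PtimCircuit([_block({"Hdac7"}, 0.8), _block({"Mcl1"}, 0.7)])
        plans = design_resistance_abrogation(circuit, self._formulary(cmax=2000.0))
        top = plans[0]
        assert top.dose_suggestions["panobinostat"] == pytest.approx(150.0)
        assert top.dose_suggestions["obatoclax"] == pytest.approx(300.0)

    def test_dose_suppressed_when_above_cmax(self):
        circuit = PtimCircuit([_block({"Hdac7"}, 0.8), _block({"Mcl1"}, 0.7)])
        plans = design_resistance_abrogation(circuit, self._formulary(cmax=250.0))
        top = plans[0]
        assert top.dose_suggestions["panobinostat"] == pytest.approx(150.0)
        assert top.dose_suggestions["obatoclax"] is None  # 300 nM > 250 nM Cmax

    def test_shared_target_blocks_not_independent(self):
        circuit = PtimCircuit([_block({"Hdac7", "X"}, 0.8), _block({"Hdac7"}, 0.7)])
        formulary = _formulary(
            {"a": {"Hdac7": 10.0, "X": 10.0}, "b": {"Hdac7": 10.0}}
        )
        assert design_resistance_abrogation(circuit, formulary) == []

    def test_pathway_map_overrides_target_disjointness(self):
        # disjoint targets but same annotated pathway: not independent
        circuit = PtimCircuit([_block({"Hdac7"}, 0.8), _block({"Mcl1"}, 0.7)])
        plans = design_resistance_abrogation(
            circuit, self._formulary(),
            pathway_map={"Hdac7": "apoptosis", "Mcl1": "apoptosis"},
        )
        assert plans == []

    def test_single_block_circuit_yields_nothing(self):
        circuit = PtimCircuit([_block({"Hdac7"}, 0.8)])
        assert design_resistance_abrogation(circuit, self._formulary()) == []


class TestFormularyValidation:
    def test_drug_without_targets_rejected(self):
        with pytest.raises(ValidationError):
            Formulary(
                drugs={"a": Drug("a", "a", max_tested_dose=100.0)},
                profiles=[],
            )
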