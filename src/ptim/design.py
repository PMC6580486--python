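"""Translate PTIM circuits into ranked two-drug combination plans.

Three clinical design questions map onto the circuit structure:

* **synergy** - pick a multi-target block and two drugs that jointly inhibit
  every target in it; each drug alone leaves the AND unsatisfied, so the
  combination should kill where monotherapy does not.
* **consensus** - for spatially distinct tumor-site models, pick one drug
  pair covering at least one block in *every* site's circuit, so the
  combination works across heterogeneous regions.
* **resistance abrogation** - pick a pair covering two *independent* blocks
  (disjoint target sets, or disjoint pathways when a target-to-pathway map is
  supplied); shutting down parallel survival routes removes escape paths.

Suggested doses follow the 1.5 x target-EC50 rule and are only emitted when
they stay at or below the drug's clinically achievable Cmax.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import InhibitionMatrix, PtimBlock, PtimCircuit, binarize_targets
from .screens import Drug, TargetProfile, ValidationError

__all__ = ["Formulary", "CombinationPlan", "cover_block", "design_synergy",
           "design_consensus", "design_resistance_abrogation"]


@dataclass
class Formulary:
    """Candidate drugs with their target profiles and dose metadata."""

    drugs: dict[str, Drug]
    profiles: list[TargetProfile]
    annotation: dict[str, str] = field(default_factory=dict)  # clinical stage etc.
    binarize_rule: str = "cmax"
    binarize_threshold: float | None = None

    def __post_init__(self) -> None:
        with_profile = {p.drug_id for p in self.profiles}
        missing = set(self.drugs) - with_profile
        if missing:
            raise ValidationError(
                f"formulary drugs without any target EC50: {sorted(missing)}"
            )
        self.matrix: InhibitionMatrix = binarize_targets(
            self.profiles, self.drugs, rule=self.binarize_rule,
            threshold=self.binarize_threshold,
        )
        self._ec50 = {(p.drug_id, p.target_id): p.ec50 for p in self.profiles}

    def inhibited(self, drug_id: str) -> frozenset[str]:
        return self.matrix.inhibited(drug_id)

    def ec50(self, drug_id: str, target_id: str) -> float | None:
        return self._ec50.get((drug_id, target_id))


@dataclass
class CombinationPlan:
    """A <=2-drug plan, the blocks it covers per model, and its score."""

    drugs: frozenset[str]
    plan_type: str  # synergy | consensus | resistance
    covered_blocks: dict[str, list[PtimBlock]]  # model_id -> covered blocks
    plan_score: float
    dose_suggestions: dict[str, float | None] = field(default_factory=dict)
    rationale: str = ""
    tightness: float = float("inf")  # max relevant EC50 over drugs; lower is tighter

    @property
    def sorted_drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.drugs))


def _verify_coverage(
    drugs: Iterable[str], block: PtimBlock, formulary: Formulary
) -> None:
    union = frozenset().union(*(formulary.inhibited(d) for d in drugs))
    if not block.targets <= union:
        raise ValidationError(
            f"stale coverage: drugs {sorted(drugs)} do not cover block "
            f"{block.sorted_targets}"
        )


def _tightness(drugs: Iterable[str], block_targets: frozenset[str], f: Formulary) -> float:
    """Max over drugs of the max EC50 on the block targets each drug covers."""
    worst = 0.0
    for d in drugs:
        relevant = [
            f.ec50(d, t) for t in block_targets if t in f.inhibited(d)
        ]
        vals = [v for v in relevant if v is not None]
        if vals:
            worst = max(worst, max(vals))
    return worst


def cover_block(
    block: PtimBlock, formulary: Formulary, max_drugs: int = 2
) -> list[frozenset[str]]:
    """All minimal drug sets (size <= max_drugs) covering every block target.

    Ranked by coverage tightness (the worst relevant EC50 across the set,
    ascending: tighter inhibition first), then drug names.  Empty when the
    block is uncoverable within the drug budget.
    """
    ids = sorted(formulary.drugs)
    inhibited = {d: formulary.inhibited(d) for d in ids}
    covers: list[frozenset[str]] = []
    singles = [d for d in ids if block.targets <= inhibited[d]]
    covers.extend(frozenset([d]) for d in singles)
    if max_drugs >= 2:
        for d1, d2 in itertools.combinations(ids, 2):
            if d1 in singles or d2 in singles:
                continue  # not minimal
            if block.targets <= inhibited[d1] | inhibited[d2]:
                covers.append(frozenset([d1, d2]))
    return sorted(
        covers, key=lambda s: (_tightness(s, block.targets, formulary), tuple(sorted(s)))
    )


def design_synergy(
    circuit: PtimCircuit,
    formulary: Formulary,
    model_id: str = "model",
    max_drugs: int = 2,
) -> list[CombinationPlan]:
    """Ranked synergy plans from multi-target blocks coverable by <= 2 drugs.

    Ranked by block score (descending), then coverage tightness (ascending),
    then drug names.  A drug set appearing for several blocks keeps its
    best-scoring block.
    """
    plans: dict[frozenset[str], CombinationPlan] = {}
    for block in circuit.blocks:
        if len(block.targets) < 2:
            continue
        for drug_set in cover_block(block, formulary, max_drugs=max_drugs):
            _verify_coverage(drug_set, block, formulary)
            existing = plans.get(drug_set)
            if existing is not None and existing.plan_score >= block.score:
                continue
            plans[drug_set] = CombinationPlan(
                drugs=drug_set,
                plan_type="synergy",
                covered_blocks={model_id: [block]},
                plan_score=block.score,
                tightness=_tightness(drug_set, block.targets, formulary),
                rationale=(
                    f"covers block {'&'.join(block.sorted_targets)} "
                    f"(score {block.score:.3f})"
                ),
            )
    return sorted(
        plans.values(), key=lambda p: (-p.plan_score, p.tightness, p.sorted_drugs)
    )


def design_consensus(
    circuits: Mapping[str, PtimCircuit],
    formulary: Formulary,
    max_drugs: int = 2,
) -> tuple[list[CombinationPlan], dict[str, bool]]:
    """Heterogeneity-consensus plans: drug sets covering a block in every model.

    plan_score is the minimum over models of the best covered-block score
    (the weakest site limits the plan).  Also returns a per-model diagnostic:
    whether any block of that model is coverable at all — when the result is
    empty, the diagnostic names the uncoverable circuits.
    """
    if len(circuits) < 2:
        raise ValidationError("consensus design needs at least two site circuits")
    ids = sorted(formulary.drugs)
    candidate_sets = [frozenset([d]) for d in ids] + [
        frozenset(pair) for pair in itertools.combinations(ids, 2)
    ]
    diagnostics = {m: False for m in circuits}
    plans: list[CombinationPlan] = []
    for drug_set in candidate_sets:
        union = frozenset().union(*(formulary.inhibited(d) for d in drug_set))
        covered: dict[str, list[PtimBlock]] = {}
        per_model_best: dict[str, float] = {}
        for model_id, circuit in circuits.items():
            hit = [b for b in circuit.blocks if b.targets <= union]
            if hit:
                diagnostics[model_id] = True
                covered[model_id] = sorted(hit, key=lambda b: -b.score)
                per_model_best[model_id] = covered[model_id][0].score
        if len(covered) < len(circuits):
            continue
        for model_id, hit in covered.items():
            _verify_coverage(drug_set, hit[0], formulary)
        worst_model = min(per_model_best, key=per_model_best.get)
        plans.append(
            CombinationPlan(
                drugs=drug_set,
                plan_type="consensus",
                covered_blocks=covered,
                plan_score=per_model_best[worst_model],
                tightness=max(
                    _tightness(drug_set, covered[m][0].targets, formulary)
                    for m in covered
                ),
                rationale=(
                    f"covers a block in all {len(circuits)} site models; "
                    f"weakest site {worst_model} "
                    f"(score {per_model_best[worst_model]:.3f})"
                ),
            )
        )
    plans.sort(key=lambda p: (-p.plan_score, p.tightness, p.sorted_drugs))
    return plans, diagnostics


def _independent(a: PtimBlock, b: PtimBlock, pathway: Mapping[str, str] | None) -> bool:
    if pathway is None:
        return not (a.targets & b.targets)
    pa = {pathway.get(t, t) for t in a.targets}
    pb = {pathway.get(t, t) for t in b.targets}
    return not (pa & pb)


def _dose_suggestions(
    drug_set: frozenset[str],
    blocks: Sequence[PtimBlock],
    formulary: Formulary,
) -> dict[str, float | None]:
    """1.5 x EC50 of each drug's relevant block target(s), emitted iff <= Cmax."""
    doses: dict[str, float | None] = {}
    for d in sorted(drug_set):
        relevant = [
            formulary.ec50(d, t)
            for b in blocks
            for t in b.targets
            if t in formulary.inhibited(d) and formulary.ec50(d, t) is not None
        ]
        if not relevant:
            doses[d] = None
            continue
        dose = 1.5 * max(relevant)  # high enough to engage the weakest relevant target
        cmax = formulary.drugs[d].cmax
        doses[d] = dose if (cmax is None or dose <= cmax) else None
    return doses


def design_resistance_abrogation(
    circuit: PtimCircuit,
    formulary: Formulary,
    pathway_map: Mapping[str, str] | None = None,
    model_id: str = "model",
    max_drugs: int = 2,
) -> list[CombinationPlan]:
    """Resistance-abrogating plans: <=2 drugs covering >=2 independent blocks.

    Independence defaults to disjoint block target sets; with a
    ``pathway_map`` (target -> pathway label) it becomes disjoint pathway
    sets.  plan_score is the minimum of the two best independent covered-
    block scores.  Suggested doses are 1.5 x the drug's relevant target EC50,
    emitted only when at or below its Cmax.
    """
    if len(circuit.blocks) < 2:
        return []
    ids = sorted(formulary.drugs)
    candidate_sets = [frozenset([d]) for d in ids] + [
        frozenset(pair) for pair in itertools.combinations(ids, 2)
    ]
    plans: list[CombinationPlan] = []
    for drug_set in candidate_sets:
        if len(drug_set) > max_drugs:
            continue
        union = frozenset().union(*(formulary.inhibited(d) for d in drug_set))
        covered = [b for b in circuit.blocks if b.targets <= union]
        best_pair: tuple[PtimBlock, PtimBlock] | None = None
        best_score = -1.0
        for a, b in itertools.combinations(covered, 2):
            if not _independent(a, b, pathway_map):
                continue
            score = min(a.score, b.score)
            if score > best_score:
                best_score, best_pair = score, (a, b)
        if best_pair is None:
            continue
        for blk in best_pair:
            _verify_coverage(drug_set, blk, formulary)
        plans.append(
            CombinationPlan(
                drugs=drug_set,
                plan_type="resistance",
                covered_blocks={model_id: list(best_pair)},
                plan_score=best_score,
                dose_suggestions=_dose_suggestions(drug_set, best_pair, formulary),
                tightness=max(
                    _tightness(drug_set, blk.targets, formulary) for blk in best_pair
                ),
                rationale=(
                    "covers independent blocks "
                    + " + ".join("&".join(b.sorted_targets) for b in best_pair)
                ),
            )
        )
    plans.sort(key=lambda p: (-p.plan_score, p.tightness, p.sorted_drugs))
    return plans


def plans_to_records(plans: Sequence[CombinationPlan]) -> list[dict]:
    """JSON/TSV-friendly plan records."""
    records = []
    for p in plans:
        records.append(
            {
                "drugs": list(p.sorted_drugs),
                "plan_type": p.plan_type,
                "plan_score": p.plan_score,
                "covered_blocks": {
                    m: [list(b.sorted_targets) for b in bs]
                    for m, bs in p.covered_blocks.items()
                },
                "dose_suggestions_nM": p.dose_suggestions,
                "rationale": p.rationale,
            }
        )
    return records
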