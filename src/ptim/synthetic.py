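"""Planted-circuit synthetic screens and omics tables, plus recovery metrics.

The generator runs the PTIM forward model in reverse: a known ground-truth
circuit (1-4-target blocks with true sensitivity scores) determines each
simulated drug's true scaled sensitivity — the best score among planted
blocks the drug fully inhibits, 0 when it covers none — and IC50s are
produced by inverting the sensitivity transform, with optional multiplicative
log-normal noise (sigma in log10 nM, matching the log-scaled transform).

Identifiability guarantees built into the default conditions:

* every planted block receives dedicated supporter drugs (default 5);
* for each planted block and each of its targets, one *decoy* drug inhibits
  the block minus that target (plus random extras completing no block), so
  every strict sub-block has a zero-sensitivity supporter and cannot
  impersonate the planted block's score;
* additional null drugs with random target sets covering no block emulate
  the inactive bulk of a screen.

Because the transform's Cmax branch collapses sensitivities in
(1 - log10(cmax)/log10(maxDose), 1) to 1, planted scores must lie below that
threshold (or be exactly 1) for the noise-free round trip to be exact; the
constructor enforces this.

Omics tables are generated so the integration rules reproduce the planted
structure: planted-block targets pass the expression-ratio and phospho rules,
single-point-of-failure targets pass the siRNA rule, and off-circuit targets
fail each rule with configurable probability (default 1, i.e. deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import PtimCircuit, inverse_scale_sensitivity
from .integration import ExpressionTable, PhosphoTable, SiRnaTable, VariantTable
from .screens import (
    ABOVE_MAX_FACTOR,
    Drug,
    ScreenResult,
    TargetProfile,
    ValidationError,
    write_drugs,
    write_screen_result,
    write_target_profiles,
)

__all__ = ["GroundTruth", "simulate_screen", "simulate_omics", "recovery_metrics",
           "write_bundle"]


def _default_blocks() -> list[tuple[frozenset[str], float]]:
    return [
        (frozenset({"T01", "T02"}), 0.70),
        (frozenset({"T03"}), 0.60),
        (frozenset({"T04", "T05", "T06"}), 0.50),
    ]


@dataclass
class GroundTruth:
    """A planted circuit plus the screen-generation conditions.

    Defaults emulate a focused kinase-inhibitor screen: a 12-target candidate
    universe, three planted blocks (sizes 2/1/3), 40 compounds inhibiting a
    truncated-geometric number of targets (mean ~3, max 8, echoing
    promiscuous kinase inhibitors), max tested dose 10 uM, Cmax 10 nM, and
    log-normal IC50 noise of 0.1 log10 units.
    """

    n_targets: int = 12
    planted_blocks: list[tuple[frozenset[str], float]] = field(
        default_factory=_default_blocks
    )
    n_drugs: int = 40
    n_supporters_per_block: int = 5
    sigma_log10: float = 0.1
    seed: int = 0
    max_tested_dose: float = 10_000.0
    cmax: float = 10.0
    mean_targets_per_drug: float = 3.0
    max_targets_per_drug: int = 8
    ec50_min: float = 1.0
    off_circuit_fail_prob: float = 1.0
    screen_id: str = "synthetic"
    model_id: str = "synthetic-model"

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_drugs < 1:
            raise ValidationError("need at least one target and one drug")
        self.targets = [f"T{i + 1:02d}" for i in range(self.n_targets)]
        universe = set(self.targets)
        threshold = 1.0 - math.log10(self.cmax) / math.log10(self.max_tested_dose)
        for targets, score in self.planted_blocks:
            if not (1 <= len(targets) <= 4):
                raise ValidationError(f"planted block must have 1-4 targets: {set(targets)}")
            if not targets <= universe:
                raise ValidationError(f"planted block outside target universe: {set(targets)}")
            if not (0.0 <= score <= 1.0):
                raise ValidationError(f"planted score must be in [0, 1]: {score}")
            if score != 1.0 and score >= threshold:
                raise ValidationError(
                    f"planted score {score} falls in the Cmax-collapsed band "
                    f"[{threshold:.3f}, 1); use a score below it or exactly 1"
                )

    @property
    def planted_targets(self) -> set[str]:
        return set().union(*(t for t, _ in self.planted_blocks))

    @property
    def single_points_of_failure(self) -> set[str]:
        return set().union(*(t for t, _ in self.planted_blocks if len(t) == 1))


def _true_sensitivity(inhibited: frozenset[str], gt: GroundTruth) -> float:
    return max(
        (score for targets, score in gt.planted_blocks if targets <= inhibited),
        default=0.0,
    )


def _covers_any(inhibited: set[str], gt: GroundTruth) -> bool:
    return any(targets <= inhibited for targets, _ in gt.planted_blocks)


def _random_target_count(rng: np.random.Generator, gt: GroundTruth) -> int:
    p = 1.0 / gt.mean_targets_per_drug
    while True:
        k = int(rng.geometric(p))
        if k <= gt.max_targets_per_drug:
            return k


def simulate_screen(
    gt: GroundTruth,
) -> tuple[dict[str, Drug], list[TargetProfile], ScreenResult, dict[str, float]]:
    """Generate one screen from a planted circuit.

    Returns (drugs, target profiles, screen result, per-drug true
    sensitivities).  At sigma_log10 = 0, re-scaling each generated IC50
    reproduces the true sensitivity exactly; drugs covering no planted block
    get an IC50 above the max tested dose and are non-hits.
    """
    rng = np.random.default_rng(gt.seed)
    universe = gt.targets
    inhibited_sets: list[frozenset[str]] = []

    # dedicated supporters per planted block; their extra targets must not
    # complete any OTHER planted block, so each block's own score is expressed
    for targets, _ in gt.planted_blocks:
        others = [(t, s) for t, s in gt.planted_blocks if t != targets]
        for _ in range(gt.n_supporters_per_block):
            extras = _random_target_count(rng, gt)
            pool = [t for t in universe if t not in targets]
            size = min(extras, len(pool))
            candidate = set(targets)
            for _ in range(50):
                extra = rng.choice(pool, size=size, replace=False) if size else np.array([])
                candidate = set(targets) | set(extra.tolist())
                if not any(ot <= candidate for ot, _ in others):
                    break
            else:  # pragma: no cover - sparse blocks make rejection rare
                candidate = set(targets)
            inhibited_sets.append(frozenset(candidate))

    # sub-block decoys: block minus one target, never completing any block
    for targets, _ in gt.planted_blocks:
        if len(targets) == 1:
            continue
        for drop in sorted(targets):
            base = set(targets) - {drop}
            pool = [t for t in universe if t not in targets]
            for _ in range(50):
                size = min(2, len(pool))
                extra = rng.choice(pool, size=size, replace=False) if size else np.array([])
                candidate = base | set(extra.tolist())
                if not _covers_any(candidate, gt):
                    break
            else:  # pragma: no cover - 12-target default never exhausts this
                candidate = base
            inhibited_sets.append(frozenset(candidate))

    # null drugs with random target sets covering no block
    while len(inhibited_sets) < gt.n_drugs:
        k = _random_target_count(rng, gt)
        for _ in range(50):
            candidate = set(rng.choice(universe, size=min(k, len(universe)), replace=False).tolist())
            if not _covers_any(candidate, gt):
                break
        else:
            candidate = {universe[int(rng.integers(len(universe)))]}
            if _covers_any(candidate, gt):  # pragma: no cover
                candidate = set()
        inhibited_sets.append(frozenset(candidate))

    drugs: dict[str, Drug] = {}
    profiles: list[TargetProfile] = []
    ic50: dict[str, float] = {}
    truth: dict[str, float] = {}
    for i, inhibited in enumerate(inhibited_sets):
        drug_id = f"D{i + 1:03d}"
        drugs[drug_id] = Drug(
            drug_id=drug_id,
            name=f"compound-{i + 1}",
            max_tested_dose=gt.max_tested_dose,
            cmax=gt.cmax,
            screen_id=gt.screen_id,
        )
        for t in sorted(inhibited):
            ec50 = float(
                np.exp(rng.uniform(np.log(gt.ec50_min), np.log(gt.cmax)))
            )
            profiles.append(TargetProfile(drug_id, t, ec50))
        y_true = _true_sensitivity(inhibited, gt)
        truth[drug_id] = y_true
        if y_true == 1.0:
            value = float(rng.uniform(0.0, gt.cmax))
            value = value if value > 0 else gt.cmax
        elif y_true > 0.0:
            value = inverse_scale_sensitivity(y_true, gt.max_tested_dose)
        else:
            value = gt.max_tested_dose * ABOVE_MAX_FACTOR
        if gt.sigma_log10 > 0:
            value = 10.0 ** (math.log10(value) + rng.normal(0.0, gt.sigma_log10))
        ic50[drug_id] = value

    screen = ScreenResult(screen_id=gt.screen_id, model_id=gt.model_id, ic50=ic50)
    return drugs, profiles, screen, truth


def simulate_omics(
    gt: GroundTruth,
) -> tuple[ExpressionTable, VariantTable, SiRnaTable, PhosphoTable]:
    """Generate omics tables consistent with the planted circuit.

    Planted-block targets over-express (tumor/normal ratio >= 1.5) and pass
    the phospho rule; single-point-of-failure targets additionally pass the
    siRNA viability rule; a random subset of planted targets carries a
    (high-impact, copy-gain) variant.  Off-circuit targets fail each rule
    with probability ``off_circuit_fail_prob``.
    """
    rng = np.random.default_rng(gt.seed + 1)
    planted = gt.planted_targets
    spof = gt.single_points_of_failure
    fails = lambda: rng.uniform() < gt.off_circuit_fail_prob  # noqa: E731

    tumor: dict[str, float] = {}
    normal: dict[str, float] = {}
    mut: dict[str, str] = {}
    cnv: dict[str, str] = {}
    viability: dict[str, float] = {}
    z1: dict[str, float] = {}
    z2: dict[str, float] = {}
    for t in gt.targets:
        base = float(rng.uniform(5.0, 50.0))
        normal[t] = base
        if t in planted:
            tumor[t] = base * float(rng.uniform(1.5, 4.0))
            mut[t], cnv[t] = (
                ("high", "gain") if rng.uniform() < 0.3 else ("none", "neutral")
            )
            z1[t] = float(rng.uniform(1.0, 3.0))
            z2[t] = z1[t] + float(rng.uniform(-0.5, 0.5))
            viability[t] = float(rng.uniform(0.2, 0.4)) if t in spof else float(
                rng.uniform(1.4, 1.8)
            )
        else:
            tumor[t] = base * (
                float(rng.uniform(0.2, 1.4)) if fails() else float(rng.uniform(1.5, 4.0))
            )
            mut[t], cnv[t] = "none", "neutral"
            z1[t] = float(rng.uniform(-1.0, 0.9)) if fails() else float(rng.uniform(1.0, 2.0))
            z2[t] = z1[t] + float(rng.uniform(-0.4, 0.4))
            viability[t] = float(rng.uniform(1.4, 1.8))
    # the knockdown-viability threshold (viability + 2*sigma < 1.5) uses the
    # whole-dataset sigma, which shifts as lethal targets are pulled down; a
    # short fixed-point pass settles both sides of the separation margin
    for _ in range(5):
        sigma = float(np.std(list(viability.values()), ddof=1))
        for t in spof:
            viability[t] = min(viability[t], max(1.5 - 2.0 * sigma - 0.05, 0.05))
    return (
        ExpressionTable(tumor=tumor, normal=normal),
        VariantTable(mut_impact=mut, cnv=cnv),
        SiRnaTable(viability=viability),
        PhosphoTable(z1=z1, z2=z2),
    )


def recovery_metrics(gt: GroundTruth, recovered: PtimCircuit) -> dict[str, float]:
    """How well a fitted circuit recovers the planted one.

    ``block_match``: fraction of planted blocks whose exact target set was
    recovered; ``target_jaccard``: Jaccard index between planted and
    recovered target unions; ``score_rmse``: RMSE of recovered vs planted
    scores over exactly-matched blocks (NaN when none matched).
    """
    planted_sets = {targets: score for targets, score in gt.planted_blocks}
    recovered_sets = {b.targets: b.score for b in recovered.blocks}
    matched = [t for t in planted_sets if t in recovered_sets]
    union_p = set().union(*planted_sets) if planted_sets else set()
    union_r = set().union(*recovered_sets) if recovered_sets else set()
    if union_p | union_r:
        jaccard = len(union_p & union_r) / len(union_p | union_r)
    else:
        jaccard = 1.0
    if matched:
        rmse = math.sqrt(
            sum((planted_sets[t] - recovered_sets[t]) ** 2 for t in matched) / len(matched)
        )
    else:
        rmse = math.nan
    return {
        "block_match": len(matched) / len(planted_sets) if planted_sets else 1.0,
        "target_jaccard": jaccard,
        "score_rmse": rmse,
    }


def write_bundle(gt: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write screen + omics tables in the TSV dialects the loaders consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drugs, profiles, screen, _ = simulate_screen(gt)
    expr, variants, sirna, phospho = simulate_omics(gt)
    paths = {name: out / f"{name}.tsv" for name in
             ("drugs", "profiles", "screen", "expression", "variants", "sirna", "phospho")}
    write_drugs(drugs, paths["drugs"])
    write_target_profiles(profiles, paths["profiles"])
    write_screen_result(screen, paths["screen"])
    import pandas as pd

    pd.DataFrame(
        [
            {"target_id": t, "tumor_expr": expr.tumor[t], "normal_expr": expr.normal[t]}
            for t in gt.targets
        ]
    ).to_csv(paths["expression"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"target_id": t, "mut_impact": variants.mut_impact[t], "cnv": variants.cnv[t]}
            for t in gt.targets
        ]
    ).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(
        [{"target_id": t, "viability": sirna.viability[t]} for t in gt.targets]
    ).to_csv(paths["sirna"], sep="\t", index=False)
    pd.DataFrame(
        [{"target_id": t, "z1": phospho.z1[t], "z2": phospho.z2[t]} for t in gt.targets]
    ).to_csv(paths["phospho"], sep="\t", index=False)
    return paths
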