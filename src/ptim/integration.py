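"""Molecular-evidence integration: per-target priors constraining model search.

Each rule converts one secondary data type (RNA expression, exome variants,
siRNA knockdown viability, phosphoproteomic z-scores) into per-target
statuses:

* ``excluded``  - removed from consideration before the search.
* ``neutral``   - no evidence either way (the default; targets absent from a
  data table are always kept for consideration).
* ``seed``      - added to the initial search conditions (candidate set at
  search start) but prunable.
* ``required``  - forced into the final model.

Independently of status, a target may be ``sticky``: once added to a model it
is kept (never pruned), without being forced in.

Rules, thresholds as applied (tumor-vs-normal expression ratio 1.5; siRNA
viability + 2*sigma < 1.5; phospho z-ratio P1 >= 1 with replicate agreement
|P1 - P2| <= 0.5; tumor-only expression at or above the first quartile) are
evaluated only over targets present both in the drug screen and in the data
table; every fired rule records its inputs in the prior's provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screens import SchemaError, ValidationError, _read_table, _require

__all__ = [
    "STATUS_ORDER",
    "TargetPrior",
    "TargetPriorSet",
    "ExpressionTable",
    "VariantTable",
    "SiRnaTable",
    "PhosphoTable",
    "rna_ratio_rule",
    "rna_quartile_rule",
    "exome_rule",
    "sirna_rule",
    "phospho_rule",
    "merge_priors",
]

logger = logging.getLogger(__name__)

STATUS_ORDER = ("excluded", "neutral", "seed", "required")
_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}

_MUT_VOCAB = {"none", "low", "med", "high"}
_CNV_VOCAB = {"loss", "neutral", "gain"}


@dataclass
class TargetPrior:
    target_id: str
    status: str = "neutral"
    sticky: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in _RANK:
            raise ValidationError(f"unknown prior status {self.status!r}")


class TargetPriorSet(dict):
    """Mapping target_id -> TargetPrior over a fixed screen target universe."""

    def __init__(self, screen_targets: Iterable[str], rule: str = "") -> None:
        super().__init__()
        self.rule = rule
        for t in screen_targets:
            self[t] = TargetPrior(t)

    def set(self, target: str, status: str, note: str, sticky: bool = False) -> None:
        prior = self[target]
        prior.status = status
        prior.sticky = prior.sticky or sticky
        prior.provenance.append(note)

    def targets_with(self, status: str) -> set[str]:
        return {t for t, p in self.items() if p.status == status}

    @property
    def excluded(self) -> set[str]:
        return self.targets_with("excluded")

    @property
    def seeds(self) -> set[str]:
        return self.targets_with("seed")

    @property
    def required(self) -> set[str]:
        return self.targets_with("required")

    @property
    def sticky(self) -> set[str]:
        return {t for t, p in self.items() if p.sticky}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target_id": t,
                    "status": p.status,
                    "sticky": p.sticky,
                    "provenance": "; ".join(p.provenance),
                }
                for t, p in sorted(self.items())
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence tables


@dataclass
class ExpressionTable:
    """Per-target expression (FPKM or equivalent, >= 0); normal optional."""

    tumor: dict[str, float]
    normal: dict[str, float] | None = None

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionTable":
        df = _read_table(path)
        _require(df, ["target_id", "tumor_expr"], path)
        tumor = {str(r["target_id"]): float(r["tumor_expr"]) for r in df.to_dict("records")}
        normal = None
        if "normal_expr" in df.columns:
            normal = {
                str(r["target_id"]): float(r["normal_expr"]) for r in df.to_dict("records")
            }
        for name, table in (("tumor", tumor), ("normal", normal or {})):
            bad = {t: v for t, v in table.items() if v < 0}
            if bad:
                raise ValidationError(f"{path}: negative {name} expression for {sorted(bad)}")
        return cls(tumor=tumor, normal=normal)


@dataclass
class VariantTable:
    """Per-target mutation impact ({none,low,med,high}) and CNV call ({loss,neutral,gain})."""

    mut_impact: dict[str, str]
    cnv: dict[str, str]

    @classmethod
    def read(cls, path: str | Path) -> "VariantTable":
        df = _read_table(path)
        _require(df, ["target_id", "mut_impact", "cnv"], path)
        mut, cnv = {}, {}
        for i, r in enumerate(df.to_dict("records"), start=2):
            t = str(r["target_id"])
            if t in mut:
                raise ValidationError(f"{path}: duplicate target {t!r} (row {i})")
            m, c = str(r["mut_impact"]), str(r["cnv"])
            if m not in _MUT_VOCAB:
                raise SchemaError(f"{path}: unknown mut_impact {m!r} (row {i})")
            if c not in _CNV_VOCAB:
                raise SchemaError(f"{path}: unknown cnv {c!r} (row {i})")
            mut[t], cnv[t] = m, c
        return cls(mut_impact=mut, cnv=cnv)


@dataclass
class SiRnaTable:
    """Per-target normalized viability after single-gene knockdown (control ~ 1)."""

    viability: dict[str, float]

    @classmethod
    def read(cls, path: str | Path) -> "SiRnaTable":
        df = _read_table(path)
        _require(df, ["target_id", "viability"], path)
        v = {str(r["target_id"]): float(r["viability"]) for r in df.to_dict("records")}
        bad = {t for t, x in v.items() if x < 0}
        if bad:
            raise ValidationError(f"{path}: negative viability for {sorted(bad)}")
        return cls(viability=v)

    @property
    def mu(self) -> float:
        return float(np.mean(list(self.viability.values())))

    @property
    def sigma(self) -> float:
        return float(np.std(list(self.viability.values()), ddof=1))


@dataclass
class PhosphoTable:
    """Per-target phospho z-score ratios vs normal, two replicates."""

    z1: dict[str, float]
    z2: dict[str, float]

    @classmethod
    def read(cls, path: str | Path) -> "PhosphoTable":
        df = _read_table(path)
        _require(df, ["target_id", "z1", "z2"], path)
        z1 = {str(r["target_id"]): float(r["z1"]) for r in df.to_dict("records")}
        z2 = {str(r["target_id"]): float(r["z2"]) for r in df.to_dict("records")}
        for table in (z1, z2):
            bad = {t for t, x in table.items() if not np.isfinite(x)}
            if bad:
                raise ValidationError(f"{path}: non-finite z-score for {sorted(bad)}")
        return cls(z1=z1, z2=z2)


# ---------------------------------------------------------------------------
# rules


def rna_ratio_rule(expr: ExpressionTable, screen_targets: Iterable[str]) -> TargetPriorSet:
    """Tumor/normal over-expression filter.

    For targets in both the screen and the expression table, the tumor/normal
    ratio must reach 1.5 (tumor expression 50% above control) to keep the
    target for consideration; below that the target is excluded.  Targets
    without expression data stay neutral.
    """
    if expr.normal is None:
        raise ValidationError("rna_ratio_rule needs normal_expr; use rna_quartile_rule")
    priors = TargetPriorSet(screen_targets, rule="rna_ratio")
    for t in priors:
        if t not in expr.tumor or t not in expr.normal:
            continue
        tumor, normal = expr.tumor[t], expr.normal[t]
        if normal == 0.0:
            if tumor > 0.0:
                priors.set(t, "neutral", f"rna_ratio: ratio=inf (tumor={tumor:g}, normal=0)")
            else:
                priors.set(t, "excluded", "rna_ratio: tumor and normal both 0")
                logger.info("rna_ratio: %s excluded (tumor and normal both zero)", t)
            continue
        ratio = tumor / normal
        if ratio >= 1.5:
            priors.set(t, "neutral", f"rna_ratio: ratio={ratio:.3g} >= 1.5, kept")
        else:
            priors.set(t, "excluded", f"rna_ratio: ratio={ratio:.3g} < 1.5")
    return priors


def rna_quartile_rule(expr: ExpressionTable, screen_targets: Iterable[str]) -> TargetPriorSet:
    """Tumor-only expression filter: keep targets at or above the first quartile.

    Q1 is the first quartile of tumor expression over screen-and-table targets
    (linear-interpolation convention by default, configurable via
    ``quantile_method``).
    """
    return _quartile_rule(expr, screen_targets, quantile_method="linear")


def _quartile_rule(
    expr: ExpressionTable, screen_targets: Iterable[str], quantile_method: str = "linear"
) -> TargetPriorSet:
    priors = TargetPriorSet(screen_targets, rule="rna_quartile")
    common = [t for t in priors if t in expr.tumor]
    if not common:
        return priors
    if len(common) < 4:
        warnings.warn("fewer than 4 targets to define a first quartile; rule skipped")
        return priors
    q1 = float(np.quantile([expr.tumor[t] for t in common], 0.25, method=quantile_method))
    for t in common:
        if expr.tumor[t] >= q1:
            priors.set(t, "neutral", f"rna_quartile: expr={expr.tumor[t]:g} >= Q1={q1:g}, kept")
        else:
            priors.set(t, "excluded", f"rna_quartile: expr={expr.tumor[t]:g} < Q1={q1:g}")
    return priors


def exome_rule(variants: VariantTable, screen_targets: Iterable[str]) -> TargetPriorSet:
    """Mutation/copy-number evidence matrix.

    high impact AND copy gain -> required (include in model); med AND gain ->
    seed (initial search conditions); high alone -> seed; med OR gain ->
    sticky (kept in model once added); otherwise neutral.
    """
    priors = TargetPriorSet(screen_targets, rule="exome")
    for t in priors:
        if t not in variants.mut_impact:
            continue
        mut, cnv = variants.mut_impact[t], variants.cnv[t]
        note = f"exome: mut={mut}, cnv={cnv}"
        if mut == "high" and cnv == "gain":
            priors.set(t, "required", note + " -> required", sticky=True)
        elif mut == "med" and cnv == "gain":
            priors.set(t, "seed", note + " -> seed", sticky=True)
        elif mut == "high":
            priors.set(t, "seed", note + " -> seed", sticky=(mut == "med" or cnv == "gain"))
        elif mut == "med" or cnv == "gain":
            priors.set(t, "neutral", note + " -> sticky", sticky=True)
    return priors


def sirna_rule(
    sirna: SiRnaTable, screen_targets: Iterable[str], variant: str = "absolute"
) -> TargetPriorSet:
    """Single-gene knockdown filter.

    Two formulations of this knockdown cutoff circulate and they do not
    select the same targets, so both are offered.  The default ``absolute``
    variant applies viability + 2*sigma < 1.5 -> required (sigma over the
    full siRNA dataset); the ``mean_centered`` variant instead requires
    viability < mu - 2*sigma (two standard deviations below the mean).
    """
    priors = TargetPriorSet(screen_targets, rule=f"sirna[{variant}]")
    if len(sirna.viability) < 2:
        warnings.warn("siRNA dataset has n < 2; sigma undefined, rule skipped")
        return priors
    mu, sigma = sirna.mu, sirna.sigma
    for t in priors:
        if t not in sirna.viability:
            continue
        v = sirna.viability[t]
        if variant == "absolute":
            fired = v + 2.0 * sigma < 1.5
            note = f"sirna: viability={v:g} + 2*sigma({sigma:.3g}) {'<' if fired else '>='} 1.5"
        elif variant == "mean_centered":
            fired = v < mu - 2.0 * sigma
            note = (
                f"sirna: viability={v:g} {'<' if fired else '>='} "
                f"mu({mu:.3g}) - 2*sigma({sigma:.3g})"
            )
        else:
            raise ValueError(f"unknown sirna rule variant {variant!r}")
        if fired:
            priors.set(t, "required", note + " -> required")
    return priors


def phospho_rule(phospho: PhosphoTable, screen_targets: Iterable[str]) -> TargetPriorSet:
    """Differential phosphorylation filter.

    A target is required when replicate 1's z-score ratio reaches 1 and the
    two replicates agree within 0.5; disagreeing or low-z targets stay
    neutral.
    """
    priors = TargetPriorSet(screen_targets, rule="phospho")
    for t in priors:
        if t not in phospho.z1:
            continue
        if t not in phospho.z2:
            warnings.warn(f"phospho: target {t} has a single replicate; skipped")
            continue
        p1, p2 = phospho.z1[t], phospho.z2[t]
        note = f"phospho: P1={p1:g}, P2={p2:g}"
        if p1 >= 1.0 and abs(p1 - p2) <= 0.5:
            priors.set(t, "required", note + " -> required")
    return priors


def merge_priors(
    priors: Sequence[TargetPriorSet], policy: str = "required_wins"
) -> TargetPriorSet:
    """Merge rule outputs with precedence excluded < neutral < seed < required.

    An explicit conflict (one rule excludes what another seeds/requires) is
    resolved per ``policy``: ``required_wins`` (default) lets the stronger
    status stand, ``excluded_wins`` drops the target; either way the conflict
    is logged into provenance.  Sticky flags are OR-ed.  An empty input yields
    an all-neutral set over an empty universe.
    """
    if policy not in {"required_wins", "excluded_wins"}:
        raise ValueError(f"unknown merge policy {policy!r}")
    universe: list[str] = []
    for ps in priors:
        for t in ps:
            if t not in universe:
                universe.append(t)
    merged = TargetPriorSet(universe, rule="merged")
    for t in universe:
        statuses = [(ps[t].status, ps.rule) for ps in priors if t in ps]
        sticky = any(ps[t].sticky for ps in priors if t in ps)
        notes = [line for ps in priors if t in ps for line in ps[t].provenance]
        has_excluded = any(s == "excluded" for s, _ in statuses)
        promotions = [s for s, _ in statuses if s in {"seed", "required"}]
        # neutral is absence of evidence: it never overrides an exclusion, and
        # only an explicit promotion (seed/required) conflicts with one
        if promotions:
            status = max(promotions, key=_RANK.__getitem__)
        elif has_excluded:
            status = "excluded"
        else:
            status = "neutral"
        if has_excluded and promotions:
            conflict = (
                f"conflict: {[r for s, r in statuses if s == 'excluded']} exclude but "
                f"{[r for s, r in statuses if s in ('seed', 'required')]} promote; "
                f"policy={policy}"
            )
            logger.warning("merge_priors: target %s %s", t, conflict)
            notes.append(conflict)
            if policy == "excluded_wins":
                status = "excluded"
        merged[t] = TargetPrior(t, status=status, sticky=sticky, provenance=notes)
    return merged
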