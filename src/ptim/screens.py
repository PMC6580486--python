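"""Drug-screen data model, tabular IO, hit classification, and screen comparison.

A *screen* is a panel of single agents tested against one cell model; its
endpoint is a per-drug IC50 (nM).  Each drug optionally carries a target
inhibition profile: per-target EC50 values (nM) quantifying how strongly the
compound inhibits individual protein targets.  All concentrations are
normalized to nM at load time; files may declare their unit per row (``nM``,
``uM``/``µM``, ``mM``, ``M``, ``pM``) in a ``unit`` column.

An IC50 above the maximum tested dose means the compound never reached 50%
growth inhibition.  Tables may either carry such values explicitly
(extrapolated fits) or use the literal cell value ``above_max``, which is
mapped to ``max_tested_dose * ABOVE_MAX_FACTOR``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ABOVE_MAX_FACTOR",
    "Drug",
    "TargetProfile",
    "ScreenResult",
    "CorrelationComparison",
    "SchemaError",
    "ValidationError",
    "load_drugs",
    "load_target_profiles",
    "load_screen_result",
    "load_screen",
    "write_drugs",
    "write_target_profiles",
    "write_screen_result",
    "classify_hits",
    "pairwise_correlations",
    "compare_screens",
]

#: Sentinel multiplier for "no 50% inhibition reached at max tested dose".
ABOVE_MAX_FACTOR = 10.0

_UNIT_TO_NM = {
    "pm": 1e-3,
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,  # greek mu
    "mm": 1e6,
    "m": 1e9,
}


class SchemaError(ValueError):
    """A mandatory column is missing or a vocabulary value is unknown."""


class ValidationError(ValueError):
    """A row violates a data invariant (e.g. non-positive concentration)."""


def _to_nm(value: float, unit: str, *, row: int | None = None) -> float:
    key = str(unit).strip().lower()
    if key not in _UNIT_TO_NM:
        raise SchemaError(f"unknown concentration unit {unit!r}" + _at(row))
    return float(value) * _UNIT_TO_NM[key]


def _at(row: int | None) -> str:
    return "" if row is None else f" (row {row})"


@dataclass(frozen=True)
class Drug:
    """A screened compound with its dose metadata.

    ``max_tested_dose`` is the highest in vitro concentration assayed (nM);
    ``cmax`` the maximum clinically achievable human plasma concentration
    (nM), or ``None`` when unknown.
    """

    drug_id: str
    name: str
    max_tested_dose: float
    cmax: float | None = None
    screen_id: str = ""

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")
        if not (self.max_tested_dose > 0):
            raise ValidationError(
                f"drug {self.drug_id}: max_tested_dose must be > 0, "
                f"got {self.max_tested_dose}"
            )
        if self.cmax is not None and not (self.cmax > 0):
            raise ValidationError(f"drug {self.drug_id}: cmax must be > 0, got {self.cmax}")


@dataclass(frozen=True)
class TargetProfile:
    """One measured drug-target interaction: EC50 (nM) of ``drug_id`` on ``target_id``.

    Absent (drug, target) pairs mean no measured interaction.
    """

    drug_id: str
    target_id: str
    ec50: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValidationError(
                f"profile ({self.drug_id}, {self.target_id}): ec50 must be > 0, got {self.ec50}"
            )


@dataclass
class ScreenResult:
    """Per-drug IC50 readout (nM) of one screen against one cell model.

    ``ic50`` may exceed a drug's max tested dose (no 50% inhibition reached).
    ``dose_response`` optionally holds raw (doses, viabilities) per drug.
    """

    screen_id: str
    model_id: str
    ic50: dict[str, float]
    dose_response: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for drug_id, value in self.ic50.items():
            if not (value > 0):
                raise ValidationError(f"drug {drug_id}: ic50 must be > 0, got {value}")


@dataclass
class CorrelationComparison:
    """Two groups of pairwise inter-model IC50 correlation coefficients.

    ``coefficients`` holds every computed pair (symmetric keys included);
    ``pairs_a``/``pairs_b`` the pair subsets compared; the t statistic is a
    two-tailed two-sample Student's t on the two coefficient groups, treating
    pairwise coefficients as independent observations.
    """

    method: str
    coefficients: dict[tuple[str, str], float]
    group_a: str
    group_b: str
    pairs_a: list[tuple[str, str]]
    pairs_b: list[tuple[str, str]]
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    unusable_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def coefficients_a(self) -> list[float]:
        return [self.coefficients[p] for p in self.pairs_a]

    @property
    def coefficients_b(self) -> list[float]:
        return [self.coefficients[p] for p in self.pairs_b]


# ---------------------------------------------------------------------------
# tabular IO


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, comment="#")


def _require(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def load_drugs(path: str | Path, screen_id: str = "") -> dict[str, Drug]:
    """Load a drug table (columns: drug_id, name, max_tested_dose, unit[, cmax])."""
    df = _read_table(path)
    _require(df, ["drug_id", "name", "max_tested_dose", "unit"], path)
    drugs: dict[str, Drug] = {}
    for i, rec in enumerate(df.to_dict("records"), start=2):  # header is line 1
        drug_id = str(rec["drug_id"])
        if drug_id in drugs:
            raise ValidationError(f"{path}: duplicate drug_id {drug_id!r}{_at(i)}")
        cmax_raw = rec.get("cmax")
        cmax = None
        if cmax_raw is not None and str(cmax_raw).strip() not in {"", "nan", "NA"}:
            cmax = _to_nm(float(cmax_raw), rec["unit"], row=i)
        try:
            drugs[drug_id] = Drug(
                drug_id=drug_id,
                name=str(rec["name"]),
                max_tested_dose=_to_nm(float(rec["max_tested_dose"]), rec["unit"], row=i),
                cmax=cmax,
                screen_id=screen_id,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}{_at(i)}: {exc}") from exc
    return drugs


def load_target_profiles(
    path: str | Path, drugs: Mapping[str, Drug] | None = None
) -> list[TargetProfile]:
    """Load a long-format drug-target EC50 table (drug_id, target_id, ec50, unit)."""
    df = _read_table(path)
    _require(df, ["drug_id", "target_id", "ec50", "unit"], path)
    profiles: list[TargetProfile] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.to_dict("records"), start=2):
        key = (str(rec["drug_id"]), str(rec["target_id"]))
        if key in seen:
            raise ValidationError(f"{path}: duplicate (drug, target) pair {key}{_at(i)}")
        seen.add(key)
        if drugs is not None and key[0] not in drugs:
            raise ValidationError(f"{path}: unknown drug_id {key[0]!r}{_at(i)}")
        try:
            profiles.append(
                TargetProfile(key[0], key[1], _to_nm(float(rec["ec50"]), rec["unit"], row=i))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}{_at(i)}: {exc}") from exc
    return profiles


def load_screen_result(
    path: str | Path,
    drugs: Mapping[str, Drug] | None = None,
    screen_id: str = "",
    model_id: str = "",
) -> ScreenResult:
    """Load a screen readout table (drug_id, ic50, unit).

    The literal ic50 value ``above_max`` is mapped to
    ``max_tested_dose * ABOVE_MAX_FACTOR`` and requires ``drugs``.
    """
    df = _read_table(path)
    _require(df, ["drug_id", "ic50", "unit"], path)
    ic50: dict[str, float] = {}
    for i, rec in enumerate(df.to_dict("records"), start=2):
        drug_id = str(rec["drug_id"])
        if drugs is not None and drug_id not in drugs:
            raise ValidationError(f"{path}: unknown drug_id {drug_id!r}{_at(i)}")
        raw = str(rec["ic50"]).strip()
        if raw == "above_max":
            if drugs is None:
                raise ValidationError(
                    f"{path}: 'above_max' sentinel needs drug dose metadata{_at(i)}"
                )
            value = drugs[drug_id].max_tested_dose * ABOVE_MAX_FACTOR
        else:
            value = _to_nm(float(raw), rec["unit"], row=i)
        if not (value > 0):
            raise ValidationError(f"{path}: ic50 must be > 0, got {value}{_at(i)}")
        ic50[drug_id] = value
    return ScreenResult(screen_id=screen_id, model_id=model_id, ic50=ic50)


def load_screen(
    drug_path: str | Path,
    profile_path: str | Path | None,
    response_path: str | Path,
    screen_id: str = "",
    model_id: str = "",
) -> tuple[dict[str, Drug], list[TargetProfile], ScreenResult]:
    """Load the drug table, target profile table, and response table of one screen."""
    drugs = load_drugs(drug_path, screen_id=screen_id)
    profiles = (
        load_target_profiles(profile_path, drugs) if profile_path is not None else []
    )
    result = load_screen_result(response_path, drugs, screen_id=screen_id, model_id=model_id)
    return drugs, profiles, result


def write_drugs(drugs: Mapping[str, Drug], path: str | Path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "name": d.name,
            "max_tested_dose": repr(d.max_tested_dose),
            "unit": "nM",
            "cmax": "" if d.cmax is None else repr(d.cmax),
        }
        for d in drugs.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_target_profiles(profiles: Iterable[TargetProfile], path: str | Path) -> None:
    rows = [
        {"drug_id": p.drug_id, "target_id": p.target_id, "ec50": repr(p.ec50), "unit": "nM"}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["drug_id", "target_id", "ec50", "unit"]).to_csv(
        path, sep="\t", index=False
    )


def write_screen_result(screen: ScreenResult, path: str | Path) -> None:
    rows = [
        {"drug_id": d, "ic50": repr(v), "unit": "nM"} for d, v in screen.ic50.items()
    ]
    pd.DataFrame(rows, columns=["drug_id", "ic50", "unit"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hit classification


def classify_hits(screen: ScreenResult, drugs: Mapping[str, Drug]) -> dict[str, bool]:
    """Classify each screened drug as a hit.

    A *hit* causes at least 50% growth inhibition at or below its maximum
    tested dose, i.e. ``ic50 <= max_tested_dose``.
    """
    hits: dict[str, bool] = {}
    for drug_id, ic50 in screen.ic50.items():
        if drug_id not in drugs:
            raise ValidationError(f"drug {drug_id!r} in screen has no dose metadata")
        hits[drug_id] = ic50 <= drugs[drug_id].max_tested_dose
    return hits


# ---------------------------------------------------------------------------
# inter-screen correlation comparison


def _pair_coefficient(
    a: ScreenResult, b: ScreenResult, method: str, min_shared: int
) -> float | None:
    shared = sorted(set(a.ic50) & set(b.ic50))
    if len(shared) < min_shared:
        return None
    xa = np.log10([a.ic50[d] for d in shared])
    xb = np.log10([b.ic50[d] for d in shared])
    if method == "spearman":
        rho = stats.spearmanr(xa, xb).statistic
    elif method == "pearson":
        rho = stats.pearsonr(xa, xb).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho)


def pairwise_correlations(
    screens: Sequence[ScreenResult], method: str = "spearman", min_shared: int = 3
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """All pairwise inter-model correlations of log10 IC50 over shared drugs.

    Returns a symmetric coefficient matrix with unit diagonal and the list of
    model pairs with fewer than ``min_shared`` shared drugs (flagged unusable,
    NaN in the matrix, never silently dropped).
    """
    ids = [s.model_id for s in screens]
    if len(ids) != len(set(ids)):
        raise ValidationError("screens must have distinct model_ids")
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    unusable: list[tuple[str, str]] = []
    for (i, sa), (j, sb) in itertools.combinations(enumerate(screens), 2):
        rho = _pair_coefficient(sa, sb, method, min_shared)
        if rho is None:
            unusable.append((ids[i], ids[j]))
            rho = math.nan
        mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat, unusable


def compare_screens(
    screens: Sequence[ScreenResult],
    grouping: Mapping[str, str],
    group_a: str,
    group_b: str | None = None,
    method: str = "spearman",
    min_shared: int = 3,
) -> CorrelationComparison:
    """Compare within-group vs between-group screen correlation.

    ``grouping`` maps model_id to a group label.  Pair set A holds all pairs
    within ``group_a``; pair set B holds pairs between ``group_a`` and
    ``group_b`` (or between ``group_a`` and any other group when ``group_b``
    is None).  The two coefficient sets are compared with a two-tailed
    two-sample Student's t-test.
    """
    if len(screens) < 2:
        raise ValidationError("need at least two screens to compare")
    mat, unusable = pairwise_correlations(screens, method=method, min_shared=min_shared)
    ids = list(mat.index)
    coeffs: dict[tuple[str, str], float] = {}
    pairs_a: list[tuple[str, str]] = []
    pairs_b: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        pair = (ids[i], ids[j])
        rho = float(mat.iloc[i, j])
        coeffs[pair] = rho
        coeffs[(pair[1], pair[0])] = rho
        if pair in unusable or math.isnan(rho):
            continue
        ga, gb = grouping.get(pair[0]), grouping.get(pair[1])
        if ga == group_a and gb == group_a:
            pairs_a.append(pair)
        elif {ga, gb} >= {group_a} and ga != gb:
            other = gb if ga == group_a else ga if gb == group_a else None
            if other is None:
                continue
            if group_b is None or other == group_b:
                pairs_b.append(pair)
    vals_a = [coeffs[p] for p in pairs_a]
    vals_b = [coeffs[p] for p in pairs_b]
    if vals_a and vals_b:
        t, p = stats.ttest_ind(vals_a, vals_b, equal_var=True)
    else:
        t, p = math.nan, math.nan
    return CorrelationComparison(
        method=method,
        coefficients=coeffs,
        group_a=group_a,
        group_b=group_b if group_b is not None else "<other>",
        pairs_a=pairs_a,
        pairs_b=pairs_b,
        mean_a=float(np.mean(vals_a)) if vals_a else math.nan,
        mean_b=float(np.mean(vals_b)) if vals_b else math.nan,
        t_statistic=float(t),
        p_value=float(p),
        unusable_pairs=unusable,
    )
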