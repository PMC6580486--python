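"""Dose-response curve fitting and Chou-Talalay combination index.

Single-agent viability curves are fit with a four-parameter logistic (4PL)
in log10-dose; drug-target EC50s bracketed by a two-concentration assay are
inferred from a fixed-asymptote Hill curve; synergy of two-drug combinations
is quantified by the non-constant-ratio combination index

    CI = d1/Dx1 + d2/Dx2,     Dx_i = Dm_i * (fa / (1 - fa))**(1 / m_i)

where (Dm, m) come from each agent's median-effect fit and (d1, d2) is a
combination dose pair producing fraction-affected fa.  CI < 1 indicates
synergy, CI = 1 additivity, CI > 1 antagonism.  CI values are only reported
inside each drug's functional dosage range [target EC50, Cmax]; outside it
they are shown as "N/A" (the value itself is never altered, only its
visibility).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .screens import ABOVE_MAX_FACTOR

__all__ = [
    "DoseResponseCurve",
    "Ec50Estimate",
    "MedianEffectFit",
    "CiResult",
    "fit_hill",
    "infer_ec50_two_point",
    "fit_median_effect",
    "combination_index",
    "functional_range_filter",
]


@dataclass
class DoseResponseCurve:
    """A fitted 4PL viability curve: v(d) = e_min + (e_max-e_min)/(1+(d/ic50)^h)."""

    e_min: float
    e_max: float
    ic50: float
    hill_slope: float
    rss: float
    above_max: bool = False  # no 50% inhibition reached; ic50 is a sentinel
    converged: bool = True

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        return self.e_min + (self.e_max - self.e_min) / (1.0 + (d / self.ic50) ** self.hill_slope)


@dataclass
class Ec50Estimate:
    """A two-point EC50 inference: value in nM or a range/monotonicity flag."""

    ec50: float | None
    status: str  # ok | above_range | below_range | non_monotone
    hill_slope: float | None = None


@dataclass
class MedianEffectFit:
    """Median-effect line fit: log(fa/fu) = m * (log d - log Dm)."""

    dm: float
    m: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.dm > 0):
            raise ValueError(f"median-effect dose Dm must be > 0, got {self.dm}")

    def iso_effective_dose(self, fa: float) -> float:
        """Single-agent dose Dx producing fraction affected ``fa``."""
        if not (0.0 < fa < 1.0):
            raise ValueError(f"fraction affected must be in (0, 1), got {fa}")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class CiResult:
    """Combination index for one (d1, d2, effect) observation."""

    d1: float
    d2: float
    effect: float
    dx1: float | None = None
    dx2: float | None = None
    ci: float | None = None
    in_functional_range: bool | str = "N/A"
    note: str = ""


def _four_pl(params: np.ndarray, log_d: np.ndarray) -> np.ndarray:
    e_min, e_max, log_ic50, h = params
    return e_min + (e_max - e_min) / (1.0 + 10.0 ** (h * (log_d - log_ic50)))


def fit_hill(
    doses: Sequence[float],
    viabilities: Sequence[float],
    n_restarts: int = 5,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
) -> DoseResponseCurve:
    """Least-squares 4PL fit with variable Hill slope in log10-dose space.

    Initialization comes from the data quartiles; ``n_restarts`` seeded random
    restarts approximate manual curation of poorly-initialized fits.  The
    ``fixed`` mapping (keys among e_min/e_max/ic50/hill_slope) is the manual
    re-fitting hook: pinned parameters are excluded from optimization.

    When the data show no 50% inhibition anywhere (all viabilities above 0.5),
    the curve is returned with ``above_max=True`` and an IC50 sentinel beyond
    the tested range.  Non-convergent fits come back flagged with rss = inf.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 dose points for a 4PL fit")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    log_d = np.log10(d)

    if v.min() > 0.5:
        # never reached 50% inhibition: sentinel IC50 above the tested range
        return DoseResponseCurve(
            e_min=float(v.min()),
            e_max=float(v.max()),
            ic50=float(d.max() * ABOVE_MAX_FACTOR),
            hill_slope=1.0,
            rss=float(np.sum((v - v.mean()) ** 2)),
            above_max=True,
            converged=False,
        )

    fixed = dict(fixed or {})
    if "ic50" in fixed:
        fixed["log_ic50"] = math.log10(fixed.pop("ic50"))
    order = ["e_min", "e_max", "log_ic50", "hill_slope"]
    lo = np.array([-0.1, -0.1, log_d.min() - 2.0, 0.05])
    hi = np.array([1.2, 1.2, log_d.max() + 2.0, 10.0])

    # quartile-based initialization
    q25, q50, q75 = np.quantile(log_d, [0.25, 0.5, 0.75])
    base = np.array([max(v.min(), -0.1), min(v.max(), 1.2), q50, 1.0])

    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_restarts):
        jitter = base + rng.normal(0.0, [0.05, 0.05, (q75 - q25) / 2 + 0.25, 0.3], size=4)
        starts.append(np.clip(jitter, lo, hi))

    free = [i for i, name in enumerate(order) if name not in fixed]

    def residuals(theta_free: np.ndarray) -> np.ndarray:
        params = np.array([fixed.get(name, math.nan) for name in order])
        params[free] = theta_free
        return _four_pl(params, log_d) - v

    best: optimize.OptimizeResult | None = None
    for start in starts:
        try:
            res = optimize.least_squares(
                residuals, start[free], bounds=(lo[free], hi[free]), method="trf"
            )
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseCurve(
            e_min=float(v.min()), e_max=float(v.max()),
            ic50=float(d.max() * ABOVE_MAX_FACTOR), hill_slope=1.0,
            rss=math.inf, above_max=True, converged=False,
        )
    params = np.array([fixed.get(name, math.nan) for name in order])
    params[free] = best.x
    e_min, e_max, log_ic50, h = params
    return DoseResponseCurve(
        e_min=float(e_min),
        e_max=float(e_max),
        ic50=float(10.0 ** log_ic50),
        hill_slope=float(h),
        rss=float(2 * best.cost),
        above_max=bool(10.0 ** log_ic50 > d.max()),
        converged=bool(best.success),
    )


def infer_ec50_two_point(
    inhibition_low: float,
    inhibition_high: float,
    dose_low: float = 100.0,
    dose_high: float = 10_000.0,
    monotone_tol: float = 0.05,
    informative: tuple[float, float] = (0.05, 0.95),
) -> Ec50Estimate:
    """Infer a drug-target EC50 from inhibition at two bracketing doses.

    Default doses are 100 nM and 10 uM.  A fixed-asymptote (0 -> 1) Hill curve
    is assumed; when both inhibitions are informative (strictly inside
    ``informative``), the slope and EC50 are solved exactly from the two
    logit equations, otherwise the slope defaults to 1 and the single
    informative point determines the EC50.  If both observations sit on one
    side of 50%, the EC50 lies outside the bracketed range and a range
    sentinel is returned instead of a number.
    """
    for label, value in (("low", inhibition_low), ("high", inhibition_high)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"inhibition_{label} must be in [0, 1], got {value}")
    if inhibition_low > inhibition_high + monotone_tol:
        warnings.warn(
            "inhibition decreases with dose beyond tolerance; no EC50 estimate",
            stacklevel=2,
        )
        return Ec50Estimate(None, "non_monotone")

    if inhibition_low >= 0.5:
        if inhibition_low == 0.5:
            return Ec50Estimate(dose_low, "ok", hill_slope=1.0)
        return Ec50Estimate(None, "below_range")
    if inhibition_high < 0.5:
        return Ec50Estimate(None, "above_range")
    if inhibition_high == 0.5:
        return Ec50Estimate(dose_high, "ok", hill_slope=1.0)

    lo_info = informative[0] < inhibition_low < informative[1]
    hi_info = informative[0] < inhibition_high < informative[1]

    def logit(x: float) -> float:
        return math.log10(x / (1.0 - x))

    if lo_info and hi_info:
        h = (logit(inhibition_high) - logit(inhibition_low)) / (
            math.log10(dose_high) - math.log10(dose_low)
        )
        log_ec50 = math.log10(dose_low) - logit(inhibition_low) / h
        return Ec50Estimate(10.0 ** log_ec50, "ok", hill_slope=h)
    if not lo_info and not hi_info:
        # ~0% then ~100%: the crossing is only bracketed; report the geometric midpoint
        return Ec50Estimate(math.sqrt(dose_low * dose_high), "ok", hill_slope=None)
    # one informative point; Hill slope fixed at 1: ec50 = d * (1 - i) / i
    d, i = (dose_high, inhibition_high) if hi_info else (dose_low, inhibition_low)
    return Ec50Estimate(d * (1.0 - i) / i, "ok", hill_slope=1.0)


def fit_median_effect(
    doses: Sequence[float], fractions_affected: Sequence[float]
) -> MedianEffectFit:
    """Fit the median-effect line log10(fa/fu) = m*(log10 d - log10 Dm).

    Observations with fa in {0, 1} are undefined on the log-linearized scale
    and are dropped with a warning.
    """
    d = np.asarray(doses, dtype=float)
    fa = np.asarray(fractions_affected, dtype=float)
    ok = (fa > 0.0) & (fa < 1.0) & (d > 0.0)
    if np.any(~ok):
        warnings.warn(
            f"{int(np.sum(~ok))} observation(s) with fa in {{0,1}} or d<=0 dropped "
            "from median-effect fit",
            stacklevel=2,
        )
    d, fa = d[ok], fa[ok]
    if d.size < 2:
        raise ValueError("need at least 2 usable points for a median-effect fit")
    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    fit = stats.linregress(x, y)
    m = float(fit.slope)
    if m <= 0:
        raise ValueError(f"median-effect slope must be positive, got {m:.4g}")
    dm = 10.0 ** (-fit.intercept / m)
    return MedianEffectFit(dm=float(dm), m=m, r2=float(fit.rvalue**2))


def combination_index(
    observations: Sequence[tuple[float, float, float]],
    mono1: MedianEffectFit,
    mono2: MedianEffectFit,
) -> list[CiResult]:
    """Non-constant-ratio combination index for (d1, d2, effect) observations.

    Uses the mutually nonexclusive two-term form CI = d1/Dx1 + d2/Dx2.
    Effects of exactly 0 or 1 leave CI undefined and are flagged, not dropped.
    """
    results: list[CiResult] = []
    for d1, d2, effect in observations:
        if not (0.0 < effect < 1.0):
            results.append(
                CiResult(d1=d1, d2=d2, effect=effect, note="effect outside (0,1); CI undefined")
            )
            continue
        dx1 = mono1.iso_effective_dose(effect)
        dx2 = mono2.iso_effective_dose(effect)
        results.append(
            CiResult(d1=d1, d2=d2, effect=effect, dx1=dx1, dx2=dx2, ci=d1 / dx1 + d2 / dx2)
        )
    return results


def functional_range_filter(
    results: Sequence[CiResult],
    target_ec50: tuple[float, float],
    cmax: tuple[float, float],
) -> list[CiResult]:
    """Annotate CI results with functional-range visibility.

    A dose pair is in range iff ec50_i <= d_i <= cmax_i for BOTH drugs (closed
    interval).  CI values are untouched; report writers render out-of-range
    rows as "N/A".  A drug whose target EC50 exceeds its Cmax has an empty
    functional range (everything N/A, warned).
    """
    for k in (0, 1):
        if target_ec50[k] > cmax[k]:
            warnings.warn(
                f"drug {k + 1}: target EC50 {target_ec50[k]:g} nM exceeds Cmax "
                f"{cmax[k]:g} nM; functional range is empty",
                stacklevel=2,
            )
    out: list[CiResult] = []
    for r in results:
        in_range = (
            target_ec50[0] <= r.d1 <= cmax[0] and target_ec50[1] <= r.d2 <= cmax[1]
        )
        out.append(replace(r, in_functional_range=bool(in_range)))
    return out


def format_ci_table(results: Sequence[CiResult]) -> str:
    """Render CI results as a TSV with N/A outside the functional range."""
    lines = ["d1_nM\td2_nM\teffect\tCI"]
    for r in results:
        if r.ci is None or r.in_functional_range is not True:
            ci = "N/A"
        else:
            ci = f"{r.ci:.4f}"
        lines.append(f"{r.d1:g}\t{r.d2:g}\t{r.effect:g}\t{ci}")
    return "\n".join(lines) + "\n"
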