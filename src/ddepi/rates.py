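"""Point prevalence, person-years incidence, and direct age standardization.

Estimates are reported the way the epidemiological literature prints
them: prevalence as a percentage of the registered, alive population on
a reference date; incidence per 1000 person-years at risk; both with
99% confidence intervals by default.  Confidence-interval methods are
Wilson (proportions), exact Poisson/Garwood (rates), and normal with
truncation at zero (directly standardized rates) — standard choices
where a study states only the confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .filters import AGE_MAX, AGE_MIN, AtRiskCohort, _first_event_dates

#: default 10-year-ish bands for age standardization and stratified rates
DEFAULT_AGE_BANDS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 200))


def age_band_label(age, bands=DEFAULT_AGE_BANDS):
    """Map ages to band labels like '25-34' ('85+' for the open band)."""
    age = np.asarray(age)
    labels = np.full(age.shape, None, dtype=object)
    for lo, hi in bands:
        lab = f"{lo}+" if hi >= 150 else f"{lo}-{hi}"
        labels[(age >= lo) & (age <= hi)] = lab
    return labels


@dataclass
class RateEstimate:
    """One rate or proportion with its confidence interval.

    ``estimate`` is per 1000 person-years for incidence and a percentage
    for prevalence; ``undefined`` marks empty denominators (the estimate
    is then NaN, never silently 0).
    """

    numerator: float
    denominator: float
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.99
    strata: dict = field(default_factory=dict)
    standardized: bool = False
    measure: str = "rate_per_1000py"
    undefined: bool = False

    def __post_init__(self):
        if not self.undefined and not (
            self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9
        ):
            raise AssertionError("confidence interval does not bracket the estimate")


def rates_to_frame(estimates) -> pd.DataFrame:
    rows = []
    for r in estimates:
        row = dict(r.strata)
        row.update(
            n_events=r.numerator,
            denominator=r.denominator,
            estimate=r.estimate,
            ci_low=r.ci_low,
            ci_high=r.ci_high,
            level=r.level,
            standardized=r.standardized,
            measure=r.measure,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _wilson(k: int, n: int, level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def poisson_exact_ci(count: int, level: float = 0.99) -> tuple[float, float]:
    """Garwood exact interval for a Poisson count (chi-square form)."""
    alpha = 1 - level
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return lo, hi


def point_prevalence(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    as_of: date,
    by: tuple = ("gender",),
    level: float = 0.99,
    age_bands=DEFAULT_AGE_BANDS,
) -> list[RateEstimate]:
    """Diagnosed proportion of the registered, alive population at ``as_of``.

    The denominator is every subject registered (reg_start <= as_of <=
    reg_end), alive, and aged 18–109 on the reference date; the
    numerator those of them with a diagnosis on or before it.  Returns
    one estimate per stratum combination of ``by`` (subset of
    {"gender", "age_band"}), plus the overall estimate, as percentages
    with Wilson intervals.
    """
    ts = pd.Timestamp(as_of)
    df = subjects.copy()
    age = ts.year - df["birth_year"]
    eligible = (
        (df["reg_start"] <= ts)
        & (df["reg_end"] >= ts)
        & (df["death_date"].isna() | (df["death_date"] > ts))
        & (age >= AGE_MIN)
        & (age <= AGE_MAX)
    )
    df = df[eligible]
    diag = _first_event_dates(events, "dd_diagnosis")
    df = df.assign(
        case=df["subject_id"].map(diag).le(ts).fillna(False),
        age_band=age_band_label(ts.year - df["birth_year"], age_bands),
    )

    out = []

    def one(sub, strata):
        n, k = len(sub), int(sub["case"].sum())
        if n == 0:
            return RateEstimate(k, 0, np.nan, np.nan, np.nan, level, strata,
                                measure="percent", undefined=True)
        lo, hi = _wilson(k, n, level)
        return RateEstimate(k, n, 100 * k / n, 100 * lo, 100 * hi, level, strata,
                            measure="percent")

    out.append(one(df, {}))
    if by:
        for key, sub in df.groupby(list(by)):
            key = key if isinstance(key, tuple) else (key,)
            out.append(one(sub, dict(zip(by, key))))
    return out


def incidence(
    at_risk: AtRiskCohort | list,
    by: tuple = (),
    level: float = 0.99,
    age_bands=DEFAULT_AGE_BANDS,
) -> list[RateEstimate]:
    """Events per 1000 person-years in year-specific at-risk cohorts.

    ``by`` may stratify on "gender" and/or "age_band" within each cohort
    (the cohort year is always a stratum label).  Exact Poisson 99%
    intervals for the count, scaled by person-years.
    """
    cohorts = at_risk if isinstance(at_risk, (list, tuple)) else [at_risk]
    out = []
    for c in cohorts:
        t = c.table.copy()
        t["age_band"] = age_band_label(t["age"], age_bands)
        t["py"] = ((t["exit"] - t["entry"]).dt.days + 1) / 365.25

        def one(sub, strata):
            py = float(sub["py"].sum())
            k = int(sub["event"].sum())
            strata = {"year": c.year, "outcome": c.outcome, **strata}
            if py <= 0:
                return RateEstimate(k, 0.0, np.nan, np.nan, np.nan, level, strata,
                                    undefined=True)
            lo, hi = poisson_exact_ci(k, level)
            return RateEstimate(k, py, 1000 * k / py, 1000 * lo / py, 1000 * hi / py,
                                level, strata)

        out.append(one(t, {}))
        if by:
            for key, sub in t.groupby(list(by)):
                key = key if isinstance(key, tuple) else (key,)
                out.append(one(sub, dict(zip(by, key))))
    return out


def pooled_age_weights(cohorts: list, age_bands=DEFAULT_AGE_BANDS) -> dict:
    """Person-year share per age band pooled over cohorts.

    This is the package's internal standard population: the pooled age
    distribution of all year-specific at-risk cohorts.  Any other
    standard (for instance the European Standard Population) can be
    supplied to :func:`direct_standardize` as a plain mapping.
    """
    tot: dict = {}
    for c in cohorts:
        t = c.table
        py = ((t["exit"] - t["entry"]).dt.days + 1) / 365.25
        bands = age_band_label(t["age"], age_bands)
        for b, v in pd.Series(py.values).groupby(bands).sum().items():
            tot[b] = tot.get(b, 0.0) + float(v)
    s = sum(tot.values())
    return {b: v / s for b, v in tot.items()}


def direct_standardize(
    stratum_rates: list[RateEstimate], standard_weights: dict, level: float = 0.99
) -> RateEstimate:
    """Directly age-standardized rate: sum of w_i * rate_i over age bands.

    Variance is sum w_i^2 * count_i / PY_i^2 (Poisson stratum variance),
    with a normal interval truncated at zero.  Every weighted band must
    be present among the stratum rates.
    """
    w = dict(standard_weights)
    if abs(sum(w.values()) - 1.0) > 1e-6:
        raise ValueError("standard weights must sum to 1")
    by_band = {r.strata.get("age_band"): r for r in stratum_rates
               if r.strata.get("age_band") is not None}
    missing = [b for b in w if b not in by_band]
    if missing:
        raise ValueError(f"age band(s) {missing} in weights but absent from rates")
    rate = 0.0
    var = 0.0
    n_events = 0.0
    py = 0.0
    strata = {}
    for b, wb in w.items():
        r = by_band[b]
        if r.undefined:
            raise ValueError(f"age band {b} has an undefined stratum rate")
        rate += wb * r.estimate  # per 1000 PY scale
        var += wb**2 * (1000.0**2 * r.numerator / r.denominator**2)
        n_events += r.numerator
        py += r.denominator
        strata = {k: v for k, v in r.strata.items() if k not in ("age_band",)}
    z = stats.norm.ppf(1 - (1 - level) / 2)
    se = np.sqrt(var)
    return RateEstimate(
        numerator=n_events,
        denominator=py,
        estimate=rate,
        ci_low=max(0.0, rate - z * se),
        ci_high=rate + z * se,
        level=level,
        strata=strata,
        standardized=True,
    )


def standardized_incidence_by_year(
    cohorts: list, level: float = 0.99, age_bands=DEFAULT_AGE_BANDS, weights: dict | None = None
) -> list[RateEstimate]:
    """Age-standardized yearly incidence across a list of at-risk cohorts.

    Uses the pooled person-year age distribution as the standard unless
    explicit ``weights`` are given.  Bands with no person-time anywhere
    are dropped from the standard (weights renormalized).
    """
    if weights is None:
        weights = pooled_age_weights(cohorts, age_bands)
    out = []
    for c in cohorts:
        strata = incidence(c, by=("age_band",), level=level, age_bands=age_bands)
        have = {r.strata.get("age_band") for r in strata} - {None}
        w = {b: v for b, v in weights.items() if b in have}
        s = sum(w.values())
        w = {b: v / s for b, v in w.items()}
        out.append(direct_standardize([r for r in strata if "age_band" in r.strata], w, level))
    return out
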