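"""Synthetic linked primary-care/hospital cohort generator.

Emulates the statistical structure of a UK EHR cohort study of Dupuytren
disease (DD): a registered population followed over a calendar window,
with

* age- and sex-specific incidence of GP-recorded DD diagnosis
  (log-quadratic age effect peaking in the 70s, higher in men),
* proportional-hazards time from diagnosis to first surgical procedure
  (covariates: male gender, age at diagnosis),
* mortality drawn from a national life table,
* registration churn (annual transfer-out probability), and
* deliberately injected record defects (missing gender, missing death
  date, diagnosis date equal to treatment date, revision-only surgical
  histories) that downstream exclusion cascades must remove.

Latent event times are simulated in continuous time by inversion over
piecewise-constant yearly hazards, then floored to day resolution, since
EHR dates are daily.  Death and transfer-out compete with diagnosis and
surgery by taking the earliest latent time.  Every draw flows from one
integer seed, so a run is fully reproducible.

All subjects are born on January 1 of their birth year (only birth year
is recorded in primary-care extracts), which makes ages constant within
calendar years and exact at year boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import LifeTable

DAYS_PER_YEAR = 365.25

EVENT_TYPES = ("dd_diagnosis", "primary_surgery", "revision_surgery")

#: English + devolved regions roughly following the GP-region mix of a
#: UK primary-care database (devolved nations lack hospital linkage).
DEFAULT_REGIONS = {
    "North East": 0.02,
    "North West": 0.13,
    "Yorkshire and the Humber": 0.045,
    "East Midlands": 0.04,
    "West Midlands": 0.09,
    "East of England": 0.09,
    "London": 0.075,
    "South West": 0.09,
    "South Central": 0.115,
    "South East Coast": 0.095,
    "Northern Ireland": 0.03,
    "Scotland": 0.085,
    "Wales": 0.095,
}

DEFAULT_COMORBIDITIES = {"diabetes": 0.17, "epilepsy": 0.019, "hypercholesterolemia": 0.11}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic cohort.

    Defaults are chosen to produce a cohort with the qualitative shape
    of the UK study population: all-ages DD diagnosis incidence around
    0.5–0.6 per 1000 person-years peaking near age 70, a male:female
    incidence rate ratio of 2, a male surgery hazard ratio of 2 and an
    age-at-diagnosis hazard ratio of 1.011 per year, and roughly one in
    eight diagnosed patients reaching first surgery within follow-up.
    """

    n_subjects: int = 50_000
    study_start: date = date(1995, 1, 1)
    study_end: date = date(2013, 12, 31)
    male_fraction: float = 0.49
    birth_year_range: tuple[int, int] = (1913, 1995)
    diagnosis_hazard_base: float = 9.3e-4
    diagnosis_age_peak: float = 70.0
    diagnosis_age_width: float = 15.0
    diagnosis_male_rate_ratio: float = 2.0
    surgery_baseline: tuple[str, dict] = ("weibull", None)
    surgery_log_hr_male: float = float(np.log(2.0))
    surgery_log_hr_age_per_year: float = 0.011
    annual_registration_exit_prob: float = 0.02
    revision_hazard: float = 0.03
    missing_gender_prob: float = 0.0
    missing_death_date_prob: float = 0.0
    diag_equals_treatment_prob: float = 0.0
    revision_only_prob: float = 0.0
    region_probs: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    comorbidity_probs: dict = field(default_factory=lambda: dict(DEFAULT_COMORBIDITIES))
    seed: int = 0

    def __post_init__(self):
        fam, params = self.surgery_baseline
        if params is None:
            params = {"rate": 0.0049} if fam == "exponential" else {"shape": 0.5, "scale": 4227.0}
            self.surgery_baseline = (fam, params)
        if fam not in ("exponential", "weibull"):
            raise ValueError(f"unknown surgery baseline family {fam!r}")
        for name in (
            "male_fraction",
            "annual_registration_exit_prob",
            "missing_gender_prob",
            "missing_death_date_prob",
            "diag_equals_treatment_prob",
            "revision_only_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.diagnosis_hazard_base < 0 or self.diagnosis_age_width <= 0:
            raise ValueError("diagnosis hazard parameters must be nonnegative (width > 0)")
        if self.diagnosis_male_rate_ratio <= 0:
            raise ValueError("diagnosis_male_rate_ratio must be > 0")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    params: dict
    latent: pd.DataFrame  # per-subject latent times, years from study start

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)


def _years_to_date(start: date, t: np.ndarray) -> pd.Series:
    """Continuous years since ``start`` floored to day resolution."""
    days = np.floor(np.asarray(t) * DAYS_PER_YEAR).astype("int64")
    return pd.Series(pd.to_datetime(start) + pd.to_timedelta(days, unit="D"))


def diagnosis_hazard(config: SimulationConfig, age, male) -> np.ndarray:
    """Yearly DD diagnosis hazard: log-quadratic in age, scaled for men."""
    age = np.asarray(age, dtype=float)
    logh = (
        np.log(max(config.diagnosis_hazard_base, 1e-300))
        - (age - config.diagnosis_age_peak) ** 2 / (2.0 * config.diagnosis_age_width**2)
    )
    h = np.exp(logh)
    if config.diagnosis_hazard_base == 0:
        h = np.zeros_like(age)
    return h * np.where(male, config.diagnosis_male_rate_ratio, 1.0)


def _invert_yearly_hazards(hazards: np.ndarray, u: np.ndarray) -> np.ndarray:
    """First-passage time (years) of a piecewise-constant yearly hazard.

    ``hazards`` is (n_subjects, n_years); returns inf where the target
    exponential deviate ``-log(u)`` is never reached inside the window.
    """
    target = -np.log(u)
    cum = np.cumsum(hazards, axis=1)
    cum_prev = np.concatenate([np.zeros((hazards.shape[0], 1)), cum[:, :-1]], axis=1)
    hit = cum >= target[:, None]
    t = np.full(hazards.shape[0], np.inf)
    rows = hit.any(axis=1)
    idx = np.argmax(hit, axis=1)
    r = np.flatnonzero(rows)
    k = idx[r]
    frac = (target[r] - cum_prev[r, k]) / hazards[r, k]
    t[r] = k + frac
    return t


def simulate_cohort(
    config: SimulationConfig, life_table: LifeTable
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate linked subject and event tables plus the ground truth.

    Returns
    -------
    subjects : DataFrame
        Columns ``subject_id, gender, birth_year, reg_start, reg_end,
        death_date, death_date_missing, region`` plus one boolean column
        per comorbidity.
    events : DataFrame
        Columns ``subject_id, event_type, event_date``; at most one
        ``dd_diagnosis`` and one ``primary_surgery`` per subject.
    truth : GroundTruth
        Generator parameters and per-subject latent times.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    y0, y1 = config.study_start.year, config.study_end.year
    n_years = y1 - y0 + 1
    horizon = ((config.study_end - config.study_start).days + 1) / DAYS_PER_YEAR

    max_sim_age = y1 - config.birth_year_range[0]
    if max_sim_age > life_table.age_max:
        raise ValueError(
            f"life table covers ages up to {life_table.age_max} but the "
            f"simulation reaches age {max_sim_age}"
        )

    birth_year = rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1, n)
    male = rng.random(n) < config.male_fraction
    gender_true = np.where(male, "male", "female")
    regions = rng.choice(
        list(config.region_probs), p=np.asarray(list(config.region_probs.values()))
        / sum(config.region_probs.values()), size=n
    )

    # ages are exact integers at calendar-year boundaries (birthday Jan 1)
    years = np.arange(y0, y1 + 1)
    ages = years[None, :] - birth_year[:, None]  # (n, n_years)

    # --- mortality, conditional on being alive (registered) at study start
    qx = np.empty((n, n_years))
    amax = life_table.age_max
    for sex in ("male", "female"):
        m = gender_true == sex
        qx[m] = life_table.qx_vector(sex, np.minimum(ages[m], amax).ravel()).reshape(
            m.sum(), n_years
        )
    h_death = -np.log(np.maximum(1.0 - qx, 1e-300))
    t_death = _invert_yearly_hazards(h_death, rng.random(n))
    t_death = np.minimum(t_death, horizon + 1.0)  # death after window is unobserved

    # --- registration exit (transfer out), geometric by year, uniform day
    p_exit = config.annual_registration_exit_prob
    h_exit = np.full((n, n_years), -np.log(max(1.0 - p_exit, 1e-300)))
    if p_exit == 0:
        t_exit = np.full(n, np.inf)
    else:
        # uniform within the exit year rather than truncated-exponential:
        # transfers are administrative, not hazard-driven
        t_raw = _invert_yearly_hazards(h_exit, rng.random(n))
        t_exit = np.where(np.isfinite(t_raw), np.floor(t_raw) + rng.random(n), np.inf)

    # --- latent DD diagnosis time
    h_diag = diagnosis_hazard(config, ages, male[:, None])
    t_diag = _invert_yearly_hazards(h_diag, rng.random(n))

    # --- latent time from diagnosis to first surgery (proportional hazards)
    age_at_start = y0 - birth_year
    age_dx = age_at_start + t_diag
    lp = config.surgery_log_hr_male * male + config.surgery_log_hr_age_per_year * np.where(
        np.isfinite(age_dx), age_dx, 0.0
    )
    e_surg = rng.exponential(size=n)
    fam, params = config.surgery_baseline
    if fam == "exponential":
        tau = e_surg / (params["rate"] * np.exp(lp))
    else:  # weibull PH: H0(t) = (t / scale) ** shape
        tau = params["scale"] * (e_surg / np.exp(lp)) ** (1.0 / params["shape"])
    t_surg = t_diag + tau
    t_rev = t_surg + (
        rng.exponential(size=n) / config.revision_hazard if config.revision_hazard > 0 else np.inf
    )

    # --- observation: censor everything at death, transfer-out, or window end
    t_censor = np.minimum.reduce([t_death, t_exit, np.full(n, horizon)])
    diag_obs = t_diag < t_censor
    surg_obs = diag_obs & (t_surg < t_censor)
    rev_obs = surg_obs & (t_rev < t_censor)
    death_obs = t_death <= np.minimum(t_exit, horizon)

    # --- defect injection
    u_def = rng.random((n, 4))
    gender = gender_true.astype(object).copy()
    gender[u_def[:, 0] < config.missing_gender_prob] = "missing"
    death_missing = death_obs & (u_def[:, 1] < config.missing_death_date_prob)
    diag_eq_treat = surg_obs & (u_def[:, 2] < config.diag_equals_treatment_prob)
    revision_only = surg_obs & (u_def[:, 3] < config.revision_only_prob)

    subject_id = np.array([f"S{i:07d}" for i in range(n)])
    reg_end_t = np.minimum(t_exit, horizon)
    # registration also closes at observed death
    reg_end_t = np.where(death_obs, np.minimum(reg_end_t, t_death), reg_end_t)

    subjects = pd.DataFrame(
        {
            "subject_id": subject_id,
            "gender": gender,
            "birth_year": birth_year,
            "reg_start": pd.Timestamp(config.study_start),
            "reg_end": _years_to_date(config.study_start, np.minimum(reg_end_t, horizon))
            .clip(upper=pd.Timestamp(config.study_end))
            .values,
            "death_date": pd.NaT,
            "death_date_missing": death_missing,
            "region": regions,
        }
    )
    dd = _years_to_date(config.study_start, np.where(death_obs, t_death, 0.0))
    dd = dd.clip(upper=pd.Timestamp(config.study_end))
    subjects.loc[death_obs & ~death_missing, "death_date"] = dd[death_obs & ~death_missing].values
    subjects["death_date"] = pd.to_datetime(subjects["death_date"])
    for name, p in config.comorbidity_probs.items():
        subjects[name] = rng.random(n) < p

    rows = []
    d_date = _years_to_date(config.study_start, np.where(diag_obs, t_diag, 0.0))
    s_date = _years_to_date(config.study_start, np.where(surg_obs, t_surg, 0.0))
    r_date = _years_to_date(config.study_start, np.where(rev_obs, t_rev, 0.0))
    for i in np.flatnonzero(diag_obs):
        ddate = s_date[i] if diag_eq_treat[i] else d_date[i]
        rows.append((subject_id[i], "dd_diagnosis", ddate))
        if surg_obs[i]:
            kind = "revision_surgery" if revision_only[i] else "primary_surgery"
            rows.append((subject_id[i], kind, s_date[i]))
            if rev_obs[i] and not revision_only[i]:
                rows.append((subject_id[i], "revision_surgery", r_date[i]))
    events = pd.DataFrame(rows, columns=["subject_id", "event_type", "event_date"])
    if events.empty:
        events = pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=object),
                "event_type": pd.Series(dtype=object),
                "event_date": pd.Series(dtype="datetime64[ns]"),
            }
        )
    events["event_date"] = pd.to_datetime(events["event_date"])

    latent = pd.DataFrame(
        {
            "subject_id": subject_id,
            "gender_true": gender_true,
            "t_diagnosis": t_diag,
            "t_surgery": t_surg,
            "t_death": t_death,
            "t_exit": t_exit,
            "age_at_diagnosis": age_dx,
        }
    )
    params = asdict(config)
    params["surgery_baseline"] = {"family": fam, **params["surgery_baseline"][1]}
    truth = GroundTruth(params=params, latent=latent)
    return subjects, events, truth


def simulate_diagnosed_cohort(
    n: int,
    male_fraction: float = 0.646,
    age_mean: float = 63.0,
    age_sd: float = 11.0,
    surgery_baseline: tuple[str, dict] = ("weibull", {"shape": 0.5, "scale": 4227.0}),
    log_hr_male: float = float(np.log(2.0)),
    log_hr_age: float = 0.011,
    censor_low: float = 1.0,
    censor_high: float = 14.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate time-to-first-surgery records for an already-diagnosed cohort.

    Produces the table consumed by the survival module directly, without
    the full population layer: gender mix and age-at-diagnosis
    distribution mimic a DD cohort (about two-thirds men, median age at
    diagnosis in the early 60s), surgery times follow the configured
    proportional-hazards model, and censoring is administrative
    (uniform follow-up between ``censor_low`` and ``censor_high`` years,
    as arises from a diagnosis date spread over a fixed calendar window).

    Returns the records plus a dict of the true parameters.
    """
    rng = np.random.default_rng(seed)
    male = rng.random(n) < male_fraction
    age = np.clip(rng.normal(age_mean, age_sd, n), 18.0, 95.0)
    lp = log_hr_male * male + log_hr_age * age
    e = rng.exponential(size=n)
    fam, params = surgery_baseline
    if fam == "exponential":
        t_event = e / (params["rate"] * np.exp(lp))
    elif fam == "weibull":
        t_event = params["scale"] * (e / np.exp(lp)) ** (1.0 / params["shape"])
    else:
        raise ValueError(f"unknown surgery baseline family {fam!r}")
    c = rng.uniform(censor_low, censor_high, n)
    records = pd.DataFrame(
        {
            "subject_id": [f"D{i:07d}" for i in range(n)],
            "time": np.minimum(t_event, c),
            "event": t_event <= c,
            "age_at_diagnosis": age,
            "gender": np.where(male, "male", "female"),
        }
    )
    truth = {
        "log_hr_male": log_hr_male,
        "log_hr_age": log_hr_age,
        "surgery_baseline": {"family": fam, **params},
        "male_fraction": male_fraction,
    }
    return records, truth


# ---------------------------------------------------------------------------
# cohort I/O: CSV with ISO-8601 dates

_DATE_COLS = {"reg_start", "reg_end", "death_date", "event_date"}


def write_cohort(subjects: pd.DataFrame, events: pd.DataFrame, path) -> None:
    """Write ``subjects.csv`` and ``events.csv`` under ``path`` (ISO dates)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    s = subjects.copy()
    for c in _DATE_COLS & set(s.columns):
        s[c] = pd.to_datetime(s[c]).dt.strftime("%Y-%m-%d")
    s.to_csv(path / "subjects.csv", index=False)
    e = events.copy()
    if len(e):
        e["event_date"] = pd.to_datetime(e["event_date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(path / "events.csv", index=False)


def _parse_dates(df: pd.DataFrame, col: str, table: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"malformed date {df[col].iloc[row]!r} in {table}.{col} at row {row}"
        )
    return parsed


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back tables written by :func:`write_cohort`, validating content."""
    path = Path(path)
    subjects = pd.read_csv(path / "subjects.csv")
    for c in ("reg_start", "reg_end", "death_date"):
        subjects[c] = _parse_dates(subjects, c, "subjects")
    events = pd.read_csv(path / "events.csv")
    if len(events):
        events["event_date"] = _parse_dates(events, "event_date", "events")
        unknown = ~events["event_type"].isin(EVENT_TYPES)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0])
            raise ValueError(
                f"unknown event_type {events['event_type'].iloc[row]!r} "
                f"in events at row {row}"
            )
    else:
        events["event_date"] = pd.to_datetime(events.get("event_date", pd.Series(dtype=object)))
    return subjects, events
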