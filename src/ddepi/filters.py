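"""Cohort construction: exclusion cascades and year-specific at-risk sets.

The base cascade removes subjects with unusable records (no recorded
gender, gone before the study window, never age-eligible, missing death
date, diagnosis date equal to treatment date).  A further cascade builds
the diagnosed cohort used for time-to-surgery and lifetime-risk
analyses: diagnosed subjects only, revision-only surgical histories
removed, diagnoses predating hospital-procedure coverage removed, and a
run-in period applied so that "incident" diagnoses are not a backlog of
prevalent cases being recorded for the first time.

Conventions: dates are closed intervals at day resolution; person-time
in years is days / 365.25; a subject whose death or registration end
falls exactly on the study start is retained ("strictly before"
exclusion); ages are exact at calendar-year boundaries because synthetic
birthdays are January 1 (see the generator), so age is constant within a
calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

AGE_MIN, AGE_MAX = 18, 109


@dataclass
class ExclusionReport:
    """Ordered record of an exclusion cascade, mirroring a flowchart."""

    initial_n: int
    steps: list = field(default_factory=list)  # (rule, n_removed, n_remaining)
    final_ids: set = field(default_factory=set)

    def add(self, rule: str, removed: int, remaining: int) -> None:
        self.steps.append((rule, int(removed), int(remaining)))

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_removed", "n_remaining"])

    def validate(self) -> None:
        n = self.initial_n
        for rule, removed, remaining in self.steps:
            if remaining != n - removed:
                raise AssertionError(f"inconsistent counts at step {rule!r}")
            n = remaining
        if self.final_ids is not None and len(self.final_ids) != n:
            raise AssertionError("final cohort size does not match cascade")


def _first_event_dates(events: pd.DataFrame, event_type: str) -> pd.Series:
    sub = events[events["event_type"] == event_type]
    return sub.groupby("subject_id")["event_date"].min()


def apply_base_exclusions(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    study_start: date,
    study_end: date,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the base record-quality cascade, in order.

    1. no recorded gender;
    2. died or left the practice strictly before the study start;
    3. never aged 18–109 during the study window;
    4. death recorded but its date missing;
    5. diagnosis date missing or equal to a treatment date (a known
       recording artefact: such "diagnoses" are surgical episodes coded
       on the day of operation).

    Defective rows are removals, never errors.  Returns the retained
    subject table and a step-by-step report.
    """
    report = ExclusionReport(initial_n=len(subjects))
    df = subjects
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)

    keep = df["gender"].isin(["male", "female"])
    df = df[keep]
    report.add("no recorded gender", (~keep).sum(), len(df))

    gone = (df["death_date"].notna() & (df["death_date"] < start)) | (df["reg_end"] < start)
    df = df[~gone]
    report.add("died or left before study start", gone.sum(), len(df))

    age_at_end = end.year - df["birth_year"]
    age_at_start = start.year - df["birth_year"]
    ineligible = (age_at_end < AGE_MIN) | (age_at_start > AGE_MAX)
    df = df[~ineligible]
    report.add("never aged 18-109 in study window", ineligible.sum(), len(df))

    miss_death = df["death_date_missing"].astype(bool)
    df = df[~miss_death]
    report.add("missing date of death", miss_death.sum(), len(df))

    diag = _first_event_dates(events, "dd_diagnosis")
    surg = events[events["event_type"].isin(["primary_surgery", "revision_surgery"])]
    surg_first = surg.groupby("subject_id")["event_date"].min()
    d = df["subject_id"].map(diag)
    s = df["subject_id"].map(surg_first)
    has_diag_row = df["subject_id"].isin(
        events.loc[events["event_type"] == "dd_diagnosis", "subject_id"]
    )
    bad_diag = (has_diag_row & d.isna()) | (d.notna() & s.notna() & (d == s))
    df = df[~bad_diag]
    report.add("missing or wrong diagnosis date", bad_diag.sum(), len(df))

    report.final_ids = set(df["subject_id"])
    report.validate()
    return df.reset_index(drop=True), report


DEVOLVED_REGIONS = ("Northern Ireland", "Scotland", "Wales")


def lifetime_risk_cohort(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    hospital_data_start: date,
    run_in_years: int = 3,
    study_end: date | None = None,
    english_only: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Restrict a base cohort to the diagnosed patients usable for
    time-to-surgery analyses.

    Removes, in order: undiagnosed subjects; subjects outside hospital-
    procedure linkage coverage (devolved-nation practices, optional);
    revision-only surgical histories (the primary operation predates the
    hospital data); diagnoses before ``hospital_data_start``; and
    diagnoses inside the run-in window ``[hospital_data_start,
    hospital_data_start + run_in_years)``.
    """
    hds = pd.Timestamp(hospital_data_start)
    if study_end is not None and hds > pd.Timestamp(study_end):
        raise ValueError("hospital_data_start falls after the study end")
    report = ExclusionReport(initial_n=len(cohort))
    df = cohort

    diag = _first_event_dates(events, "dd_diagnosis")
    diagnosed = df["subject_id"].isin(diag.index)
    df = df[diagnosed]
    report.add("not diagnosed with DD", (~diagnosed).sum(), len(df))

    if english_only:
        devolved = df["region"].isin(DEVOLVED_REGIONS)
        df = df[~devolved]
        report.add("no hospital linkage (devolved nation)", devolved.sum(), len(df))

    prim = set(events.loc[events["event_type"] == "primary_surgery", "subject_id"])
    rev = set(events.loc[events["event_type"] == "revision_surgery", "subject_id"])
    rev_only = df["subject_id"].isin(rev - prim)
    df = df[~rev_only]
    report.add("revision surgery only", rev_only.sum(), len(df))

    d = df["subject_id"].map(diag)
    pre_hes = d < hds
    df = df[~pre_hes]
    report.add("diagnosed before hospital data start", pre_hes.sum(), len(df))

    analysis_start = hds + pd.DateOffset(years=run_in_years)
    run_in = df["subject_id"].map(diag) < analysis_start
    df = df[~run_in]
    report.add(f"diagnosed in {run_in_years}-year run-in", run_in.sum(), len(df))

    report.final_ids = set(df["subject_id"])
    report.validate()
    return df.reset_index(drop=True), report


def time_to_event_records(
    cohort: pd.DataFrame, events: pd.DataFrame, study_end: date
) -> pd.DataFrame:
    """Build time-from-diagnosis-to-first-surgery records for a diagnosed cohort.

    Time is in years (days / 365.25) from diagnosis to primary surgery,
    or to censoring at the earliest of death, registration end, and the
    study end.  Zero or negative durations cannot occur for subjects
    passing the base cascade (diagnosis-equals-treatment rows were
    removed); they raise if present.
    """
    diag = _first_event_dates(events, "dd_diagnosis")
    surg = _first_event_dates(events, "primary_surgery")
    df = cohort.copy()
    df["diagnosis_date"] = df["subject_id"].map(diag)
    if df["diagnosis_date"].isna().any():
        raise ValueError("cohort contains undiagnosed subjects")
    df["surgery_date"] = df["subject_id"].map(surg)
    end = pd.Timestamp(study_end)
    censor = pd.concat(
        [df["reg_end"].fillna(end).clip(upper=end), df["death_date"].fillna(end)], axis=1
    ).min(axis=1)
    event = df["surgery_date"].notna() & (df["surgery_date"] <= censor)
    stop = df["surgery_date"].where(event, censor)
    time = (stop - df["diagnosis_date"]).dt.days / DAYS_PER_YEAR
    if (time[event] <= 0).any():
        raise ValueError("nonpositive diagnosis-to-surgery time; cascade not applied?")
    birth = pd.to_datetime(dict(year=df["birth_year"], month=1, day=1))
    age_dx = (df["diagnosis_date"] - birth).dt.days / DAYS_PER_YEAR
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].values,
            "time": time.clip(lower=0.5 / DAYS_PER_YEAR).values,
            "event": event.values,
            "age_at_diagnosis": age_dx.values,
            "gender": df["gender"].values,
        }
    )
    return out


@dataclass
class AtRiskCohort:
    """Population at risk of an outcome in one calendar year.

    ``table`` has one row per at-risk subject: entry/exit dates (closed
    interval), event flag, exit reason, gender, and age in the year.
    """

    year: int
    outcome: str
    table: pd.DataFrame

    @property
    def person_days(self) -> int:
        if self.table.empty:
            return 0
        return int(((self.table["exit"] - self.table["entry"]).dt.days + 1).sum())

    @property
    def person_years(self) -> float:
        return self.person_days / DAYS_PER_YEAR

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())


OUTCOMES = ("diagnosis", "first_surgery")


def year_at_risk_cohort(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    year: int,
    outcome: str = "diagnosis",
    denominator: str = "population",
) -> AtRiskCohort:
    """Build the population at risk of ``outcome`` during ``year``.

    Subjects with the outcome before January 1 are excluded.  Entry is
    the latest of January 1, registration start, and the 18th birthday;
    exit the earliest of the outcome date, death, registration end, age
    110, and December 31.  For ``outcome="first_surgery"`` the default
    denominator is the full eligible population without prior surgery;
    ``denominator="diagnosed"`` instead restricts to diagnosed subjects,
    entering at diagnosis.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if denominator not in ("population", "diagnosed"):
        raise ValueError(f"unknown denominator {denominator!r}")
    ev_type = "dd_diagnosis" if outcome == "diagnosis" else "primary_surgery"
    out_date = _first_event_dates(events, ev_type)

    jan1 = pd.Timestamp(date(year, 1, 1))
    dec31 = pd.Timestamp(date(year, 12, 31))
    df = cohort.copy()
    age = year - df["birth_year"]
    df = df[(age >= AGE_MIN) & (age <= AGE_MAX)]

    od = df["subject_id"].map(out_date)
    df = df[~(od <= jan1 - pd.Timedelta(days=1))]
    od = df["subject_id"].map(out_date)

    entry = df["reg_start"].clip(lower=jan1)
    if denominator == "diagnosed" and outcome == "first_surgery":
        ddate = df["subject_id"].map(_first_event_dates(events, "dd_diagnosis"))
        keep = ddate.notna()
        df, od, entry, ddate = df[keep], od[keep], entry[keep], ddate[keep]
        entry = pd.concat([entry, ddate], axis=1).max(axis=1)

    exit_candidates = pd.DataFrame(
        {
            "outcome": od,
            "death": df["death_date"],
            "transfer": df["reg_end"],
            "year_end": dec31,
        }
    )
    exit_date = exit_candidates.min(axis=1)
    reason = exit_candidates.idxmin(axis=1).map(
        {
            "outcome": "diagnosed/treated",
            "death": "died",
            "transfer": "transferred out",
            "year_end": "year end",
        }
    )
    ok = entry <= exit_date
    table = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "entry": entry,
            "exit": exit_date,
            "event": od.notna() & (od <= exit_date),
            "exit_reason": reason,
            "gender": df["gender"],
            "age": year - df["birth_year"],
        }
    )[ok].reset_index(drop=True)
    return AtRiskCohort(year=year, outcome=outcome, table=table)
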