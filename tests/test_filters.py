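from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ddepi import (
    SimulationConfig,
    apply_base_exclusions,
    lifetime_risk_cohort,
    simulate_cohort,
    time_to_event_records,
    year_at_risk_cohort,
)


def _subject(sid, gender="male", birth_year=1950, reg_start="1995-01-01",
             reg_end="2013-12-31", death=None, death_missing=False, region="London"):
    return {
        "subject_id": sid,
        "gender": gender,
        "birth_year": birth_year,
        "reg_start": pd.Timestamp(reg_start),
        "reg_end": pd.Timestamp(reg_end),
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "death_date_missing": death_missing,
        "region": region,
    }


def _events(rows):
    return pd.DataFrame(rows, columns=["subject_id", "event_type", "event_date"]).assign(
        event_date=lambda d: pd.to_datetime(d["event_date"])
    )


START, END = date(1995, 1, 1), date(2013, 12, 31)


def test_defect_free_cascade_removes_nothing(clean_cohort, study_window):
    subjects, events, _, _ = clean_cohort
    _, report = apply_base_exclusions(subjects, events, *study_window)
    assert report.to_frame()["n_removed"].sum() == 0
    assert report.final_n == len(subjects)


def test_each_rule_removes_its_subject():
    subjects = pd.DataFrame(
        [
            _subject("ok"),
            _subject("nogender", gender="missing"),
            _subject("gone", reg_end="1994-06-01"),
            _subject("tooyoung", birth_year=1999),
            _subject("nodeath", death_missing=True),
            _subject("diag_eq_treat"),
        ]
    )
    events = _events(
        [
            ("ok", "dd_diagnosis", "2005-03-01"),
            ("diag_eq_treat", "dd_diagnosis", "2006-07-01"),
            ("diag_eq_treat", "primary_surgery", "2006-07-01"),
        ]
    )
    cohort, report = apply_base_exclusions(subjects, events, START, END)
    removed = dict(zip(report.to_frame()["rule"], report.to_frame()["n_removed"]))
    assert removed == {
        "no recorded gender": 1,
        "died or left before study start": 1,
        "never aged 18-109 in study window": 1,
        "missing date of death": 1,
        "missing or wrong diagnosis date": 1,
    }
    assert set(cohort["subject_id"]) == {"ok"}


def test_boundary_conventions():
    """Death or deregistration exactly on the study start is retained;
    a subject turning 18 in the final study year is retained."""
    subjects = pd.DataFrame(
        [
            _subject("edge_death", death="1995-01-01"),
            _subject("edge_reg", reg_end="1995-01-01"),
            _subject("turns18", birth_year=1995),
        ]
    )
    cohort, _ = apply_base_exclusions(subjects, _events([]), START, END)
    assert set(cohort["subject_id"]) == {"edge_death", "edge_reg", "turns18"}


def test_cascade_final_cohort_invariant_to_order_for_single_violations():
    """When each subject violates at most one rule, the final cohort does
    not depend on cascade order (checked against a one-rule-at-a-time
    reference)."""
    subjects = pd.DataFrame(
        [
            _subject("a"),
            _subject("b", gender="missing"),
            _subject("c", death_missing=True),
            _subject("d", reg_end="1993-01-01"),
        ]
    )
    events = _events([])
    cohort, _ = apply_base_exclusions(subjects, events, START, END)
    # reference: intersect survivors of each rule applied independently
    ref = set(subjects["subject_id"])
    ref &= set(subjects.loc[subjects["gender"].isin(["male", "female"]), "subject_id"])
    ref &= set(subjects.loc[~subjects["death_date_missing"], "subject_id"])
    ref &= set(subjects.loc[subjects["reg_end"] >= pd.Timestamp(START), "subject_id"])
    assert set(cohort["subject_id"]) == ref


def test_exclusion_counts_within_binomial_bounds(life_table, study_window):
    """Defect injection at 1% lands within binomial 99% bounds per step."""
    cfg = SimulationConfig(
        n_subjects=10_000,
        seed=13,
        missing_gender_prob=0.01,
        missing_death_date_prob=0.01,
        diag_equals_treatment_prob=0.01,
        revision_only_prob=0.01,
    )
    subjects, events, _ = simulate_cohort(cfg, life_table)
    _, report = apply_base_exclusions(subjects, events, *study_window)
    removed = dict(zip(report.to_frame()["rule"], report.to_frame()["n_removed"]))

    def bounds(n, p=0.01):
        return stats.binom.ppf(0.005, n, p), stats.binom.ppf(0.995, n, p)

    lo, hi = bounds(len(subjects))
    assert lo <= removed["no recorded gender"] <= hi
    # eligible for the missing-death-date flag: recorded deaths surviving
    # the earlier steps
    survivors = subjects[subjects["gender"].isin(["male", "female"])]
    n_dead = int((survivors["death_date"].notna() | survivors["death_date_missing"]).sum())
    lo, hi = bounds(n_dead)
    assert lo <= removed["missing date of death"] <= hi


def test_lifetime_cohort_rules():
    subjects = pd.DataFrame(
        [
            _subject("kept"),
            _subject("undiag"),
            _subject("revonly"),
            _subject("early_dx"),
            _subject("run_in_dx"),
            _subject("scottish", region="Scotland"),
        ]
    )
    events = _events(
        [
            ("kept", "dd_diagnosis", "2005-05-05"),
            ("kept", "primary_surgery", "2007-01-01"),
            ("revonly", "dd_diagnosis", "2004-01-01"),
            ("revonly", "revision_surgery", "2006-01-01"),
            ("early_dx", "dd_diagnosis", "1996-12-31"),
            ("run_in_dx", "dd_diagnosis", "1999-12-31"),
            ("scottish", "dd_diagnosis", "2005-01-01"),
        ]
    )
    dd, report = lifetime_risk_cohort(
        subjects, events, date(1997, 1, 1), run_in_years=3, study_end=END
    )
    assert set(dd["subject_id"]) == {"kept"}
    removed = dict(zip(report.to_frame()["rule"], report.to_frame()["n_removed"]))
    assert removed["not diagnosed with DD"] == 1
    assert removed["revision surgery only"] == 1
    assert removed["diagnosed before hospital data start"] == 1
    assert removed["diagnosed in 3-year run-in"] == 1
    assert removed["no hospital linkage (devolved nation)"] == 1


def test_lifetime_cohort_set_algebra_oracle(life_table, study_window):
    """Cascade result equals an independent set computation on 1,000 subjects."""
    cfg = SimulationConfig(n_subjects=1000, seed=21, revision_only_prob=0.2)
    subjects, events, _ = simulate_cohort(cfg, life_table)
    cohort, _ = apply_base_exclusions(subjects, events, *study_window)
    dd, _ = lifetime_risk_cohort(cohort, events, date(1997, 1, 1), 3, study_end=END)

    diag = events[events.event_type == "dd_diagnosis"].set_index("subject_id")["event_date"]
    prim = set(events.loc[events.event_type == "primary_surgery", "subject_id"])
    rev = set(events.loc[events.event_type == "revision_surgery", "subject_id"])
    expected = (
        set(cohort["subject_id"])
        & set(diag.index)
        - (rev - prim)
        - set(diag[diag < pd.Timestamp("2000-01-01")].index)
        - set(cohort.loc[cohort.region.isin(["Scotland", "Wales", "Northern Ireland"]),
                         "subject_id"])
    )
    assert set(dd["subject_id"]) == expected


def test_hospital_start_after_study_end_fails():
    with pytest.raises(ValueError, match="after the study end"):
        lifetime_risk_cohort(
            pd.DataFrame([_subject("a")]), _events([]), date(2020, 1, 1), study_end=END
        )


class TestYearAtRisk:
    def test_prior_year_case_absent(self):
        subjects = pd.DataFrame([_subject("old_case"), _subject("new_case")])
        events = _events(
            [
                ("old_case", "dd_diagnosis", "2004-06-01"),
                ("new_case", "dd_diagnosis", "2005-06-01"),
            ]
        )
        arc = year_at_risk_cohort(subjects, events, 2005, "diagnosis")
        assert set(arc.table["subject_id"]) == {"new_case"}
        assert arc.n_events == 1

    def test_midyear_registration_contributes_at_most_184_days(self):
        subjects = pd.DataFrame([_subject("july", reg_start="2005-07-01")])
        arc = year_at_risk_cohort(subjects, _events([]), 2005, "diagnosis")
        assert arc.person_days == 184

    def test_exit_reasons_and_event_flag(self):
        subjects = pd.DataFrame(
            [
                _subject("dies", death="2005-03-15"),
                _subject("leaves", reg_end="2005-10-01"),
                _subject("case"),
            ]
        )
        events = _events([("case", "dd_diagnosis", "2005-08-08")])
        arc = year_at_risk_cohort(subjects, events, 2005, "diagnosis")
        t = arc.table.set_index("subject_id")
        assert t.loc["dies", "exit_reason"] == "died"
        assert t.loc["leaves", "exit_reason"] == "transferred out"
        assert t.loc["case", "exit_reason"] == "diagnosed/treated"
        assert bool(t.loc["case", "event"]) and not bool(t.loc["dies", "event"])

    def test_person_days_match_calendar_enumeration(self, life_table, study_window):
        cfg = SimulationConfig(n_subjects=500, seed=31)
        subjects, events, _ = simulate_cohort(cfg, life_table)
        cohort, _ = apply_base_exclusions(subjects, events, *study_window)
        arc = year_at_risk_cohort(cohort, events, 2005, "diagnosis")
        days = pd.date_range("2005-01-01", "2005-12-31", freq="D")
        diag = events[events.event_type == "dd_diagnosis"].set_index("subject_id")["event_date"]
        total = 0
        for _, row in cohort.iterrows():
            d = diag.get(row["subject_id"], pd.NaT)
            if pd.notna(d) and d < days[0]:
                continue
            age = 2005 - row["birth_year"]
            if not 18 <= age <= 109:
                continue
            alive = row["death_date"] if pd.notna(row["death_date"]) else days[-1]
            mask = (days >= row["reg_start"]) & (days <= row["reg_end"]) & (days <= alive)
            if pd.notna(d):
                mask &= days <= d
            total += int(mask.sum())
        assert arc.person_days == total

    def test_monthly_split_additivity(self):
        """Splitting a subject's in-year interval at month boundaries and
        summing the pieces reproduces the annual person-days exactly."""
        subjects = pd.DataFrame([_subject("s", reg_start="2005-03-17", reg_end="2005-11-02")])
        arc = year_at_risk_cohort(subjects, _events([]), 2005, "diagnosis")
        row = arc.table.iloc[0]
        months = pd.date_range("2005-01-01", "2006-01-01", freq="MS")
        pieces = 0
        for m0, m1 in zip(months[:-1], months[1:]):
            lo, hi = max(row["entry"], m0), min(row["exit"], m1 - pd.Timedelta(days=1))
            if lo <= hi:
                pieces += (hi - lo).days + 1
        assert pieces == arc.person_days

    def test_surgery_outcome_denominators(self):
        subjects = pd.DataFrame([_subject("dx"), _subject("plain")])
        events = _events(
            [("dx", "dd_diagnosis", "2005-04-01"), ("dx", "primary_surgery", "2005-09-01")]
        )
        pop = year_at_risk_cohort(subjects, events, 2005, "first_surgery", "population")
        assert set(pop.table["subject_id"]) == {"dx", "plain"}
        assert pop.n_events == 1
        diag = year_at_risk_cohort(subjects, events, 2005, "first_surgery", "diagnosed")
        assert set(diag.table["subject_id"]) == {"dx"}
        t = diag.table.iloc[0]
        assert t["entry"] == pd.Timestamp("2005-04-01")
        assert t["exit"] == pd.Timestamp("2005-09-01")

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            year_at_risk_cohort(pd.DataFrame([_subject("a")]), _events([]), 2005, "relapse")


def test_time_to_event_records_hand_case():
    subjects = pd.DataFrame(
        [_subject("surg"), _subject("cens", death="2010-06-30")]
    )
    events = _events(
        [
            ("surg", "dd_diagnosis", "2005-01-01"),
            ("surg", "primary_surgery", "2006-01-01"),
            ("cens", "dd_diagnosis", "2008-06-30"),
        ]
    )
    rec = time_to_event_records(subjects, events, END).set_index("subject_id")
    assert rec.loc["surg", "event"]
    assert rec.loc["surg", "time"] == pytest.approx(365 / 365.25)
    assert not rec.loc["cens", "event"]
    assert rec.loc["cens", "time"] == pytest.approx(730 / 365.25)
    assert rec.loc["surg", "age_at_diagnosis"] == pytest.approx(55.0, abs=0.05)
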