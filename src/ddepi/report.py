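"""End-to-end pipeline orchestration and publication-style outputs.

``run_all`` drives: simulate (or ingest) → exclusion cascades → point
prevalence and yearly incidence (diagnosis and first surgery, crude and
age-standardized) → Kaplan–Meier curves and survival fits → multistate
Markov lifetime-risk grid → CSV artifacts plus a manifest with hashes,
so a rerun under the same config and seed is bit-identical.

Percentages in the demographic table are 100·part/whole rounded to one
decimal (display convention); the underlying CSVs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filters, rates, simulate, survival, markov
from .lifetable import LifeTable, load_life_table, packaged_life_table, write_life_table

logger = logging.getLogger(__name__)


def percentage(part: float, whole: float) -> float:
    """Display percentage: 100 * part / whole rounded to one decimal."""
    if whole == 0:
        return float("nan")
    return round(100.0 * part / whole, 1)


def summarize_demographics(cohort: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Characteristics of the diagnosed cohort and its surgically treated subset.

    One row per characteristic with counts and percentages for all DD
    patients and for those having first surgical treatment; ages are
    medians with interquartile ranges.
    """
    diag = filters._first_event_dates(events, "dd_diagnosis")
    surg = filters._first_event_dates(events, "primary_surgery")
    dd = cohort[cohort["subject_id"].isin(diag.index)].copy()
    dd["diagnosis_date"] = dd["subject_id"].map(diag)
    dd["surgery_date"] = dd["subject_id"].map(surg)
    treated = dd[dd["surgery_date"].notna()]

    birth = lambda df: pd.to_datetime(dict(year=df["birth_year"], month=1, day=1))
    age_dx = (dd["diagnosis_date"] - birth(dd)).dt.days / 365.25
    age_tx = (treated["surgery_date"] - birth(treated)).dt.days / 365.25

    rows = [("No.", "", len(dd), np.nan, len(treated), np.nan)]

    def count_rows(label, mask_dd, mask_tx):
        rows.append(
            (label, "", int(mask_dd.sum()), percentage(mask_dd.sum(), len(dd)),
             int(mask_tx.sum()), percentage(mask_tx.sum(), len(treated)))
        )

    for g in ("male", "female"):
        count_rows(f"Gender: {g}", dd["gender"] == g, treated["gender"] == g)

    def iqr_rows(label, s_dd, s_tx):
        med = lambda s: np.nan if len(s) == 0 else float(np.median(s))
        q = lambda s, p: np.nan if len(s) == 0 else float(np.quantile(s, p))
        rows.append((f"{label}: median", "", med(s_dd), np.nan, med(s_tx), np.nan))
        rows.append((f"{label}: IQR low", "", q(s_dd, 0.25), np.nan, q(s_tx, 0.25), np.nan))
        rows.append((f"{label}: IQR high", "", q(s_dd, 0.75), np.nan, q(s_tx, 0.75), np.nan))

    iqr_rows("Age at diagnosis (yr)", age_dx, (treated["diagnosis_date"] - birth(treated)).dt.days / 365.25)
    iqr_rows("Age at first treatment (yr)", pd.Series(dtype=float), age_tx)

    for region in sorted(dd["region"].unique()):
        count_rows(f"Region: {region}", dd["region"] == region, treated["region"] == region)
    for com in ("diabetes", "epilepsy", "hypercholesterolemia"):
        if com in dd.columns:
            count_rows(com.capitalize(), dd[com].astype(bool), treated[com].astype(bool))

    return pd.DataFrame(
        rows, columns=["characteristic", "detail", "dd_n", "dd_pct", "treated_n", "treated_pct"]
    )


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run; one seed governs everything."""

    out_dir: str = "ddepi_run"
    cohort_dir: str | None = None          # ingest instead of simulating
    life_table_path: str | None = None     # default: packaged synthetic table
    # demo scale: large enough that the diagnosed cohort supports the
    # parametric fits (>= 30 surgery events)
    simulation: dict = field(default_factory=lambda: {"n_subjects": 150_000})
    study_start: date = date(1995, 1, 1)
    study_end: date = date(2013, 12, 31)
    hospital_data_start: date = date(1997, 1, 1)
    run_in_years: int = 3
    ci_level: float = 0.99
    families: tuple = ("exponential", "weibull", "spline-3")
    chosen_family: str | None = "spline-3"
    sweep_ages: tuple = tuple(range(40, 91, 5))
    cycle_years: float = 1.0 / 12.0
    bootstrap_replicates: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("study_start", "study_end", "hospital_data_start"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        for key in ("families", "sweep_ages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every pipeline stage and write all artifacts under ``out_dir``.

    Returns the output directory.  Any stage failure aborts with the
    stage name attached to the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        life = (
            load_life_table(config.life_table_path)
            if config.life_table_path
            else packaged_life_table()
        )
        write_life_table(life, out / "lifetable.csv")

        stage = "simulate/ingest"
        if config.cohort_dir:
            subjects, events = simulate.read_cohort(config.cohort_dir)
        else:
            sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)
            subjects, events, truth = simulate.simulate_cohort(sim_cfg, life)
            simulate.write_cohort(subjects, events, out)
            truth.to_json(out / "truth.json")
        logger.info("stage %s: %d subjects, %d events", stage, len(subjects), len(events))

        stage = "base exclusions"
        cohort, base_report = filters.apply_base_exclusions(
            subjects, events, config.study_start, config.study_end
        )
        base_report.to_frame().to_csv(out / "exclusions_base.csv", index=False)
        logger.info("stage %s: %d -> %d", stage, base_report.initial_n, base_report.final_n)

        stage = "prevalence"
        prev = rates.point_prevalence(
            cohort, events, config.study_end, by=("gender",), level=config.ci_level
        )
        rates.rates_to_frame(prev).to_csv(out / "prevalence.csv", index=False)

        stage = "incidence"
        first_year = config.hospital_data_start.year + config.run_in_years
        years = range(first_year, config.study_end.year + 1)
        for outcome, fname in (("diagnosis", "incidence_diagnosis.csv"),
                               ("first_surgery", "incidence_surgery.csv")):
            cohorts = [
                filters.year_at_risk_cohort(cohort, events, y, outcome) for y in years
            ]
            crude = rates.incidence(cohorts, by=("gender",), level=config.ci_level)
            std = rates.standardized_incidence_by_year(cohorts, level=config.ci_level)
            rates.rates_to_frame(crude + std).to_csv(out / fname, index=False)

        stage = "lifetime-risk cohort"
        dd_cohort, lr_report = filters.lifetime_risk_cohort(
            cohort, events, config.hospital_data_start, config.run_in_years,
            study_end=config.study_end,
        )
        lr_report.to_frame().to_csv(out / "exclusions_lifetime.csv", index=False)
        summarize_demographics(cohort, events).to_csv(out / "table1.csv", index=False)
        records = filters.time_to_event_records(dd_cohort, events, config.study_end)

        stage = "Kaplan-Meier"
        km_frames = []
        for by in (None, "gender", "age_quartile"):
            for name, frame in survival.km_one_minus_survival(records, by=by).items():
                frame = frame.assign(stratum=name, stratifier=by or "all")
                km_frames.append(frame)
        pd.concat(km_frames, ignore_index=True).to_csv(out / "km_curves.csv", index=False)

        stage = "Cox PH"
        cox = survival.fit_proportional_hazards(records)
        cox.summary.to_csv(out / "cox_summary.csv")

        stage = "parametric fits"
        fits = [survival.fit_parametric(records, fam) for fam in config.families]
        sel = survival.select_model(
            fits, records, horizon=100.0, override=config.chosen_family
        )
        sel.ranking.to_csv(out / "model_selection.csv", index=False)
        sel.extrapolation.to_csv(out / "extrapolation.csv", index=False)
        chosen = sel.best
        if isinstance(chosen, survival.SplineSurvivalFit):
            with open(out / "fit.json", "w") as fh:
                json.dump(chosen.to_dict(), fh, indent=2)

        stage = "Markov lifetime risk"
        mk_cfg = markov.MarkovConfig(
            cycle_years=config.cycle_years,
            bootstrap_replicates=config.bootstrap_replicates,
            ci_level=config.ci_level,
            seed=config.seed,
        )
        if config.bootstrap_replicates > 0:
            profiles = [
                markov.PatientProfile(g, a)
                for g in ("male", "female")
                for a in config.sweep_ages
            ]
            res = markov.bootstrap_lifetime_risk(
                records, life, profiles, mk_cfg, family=chosen.family
            )
            sweep = pd.DataFrame(
                [
                    {
                        "gender": r.profile.gender,
                        "age_at_diagnosis": r.profile.age_at_diagnosis,
                        "lifetime_risk": r.lifetime_risk,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                    }
                    for r in res
                ]
            )
        else:
            sweep = markov.profile_sweep(chosen, life, mk_cfg, ages=config.sweep_ages)
        sweep.to_csv(out / "lifetime.csv", index=False)

        stage = "manifest"
        artifacts = sorted(p for p in out.glob("*.csv")) + sorted(out.glob("*.json"))
        manifest = {
            "seed": config.seed,
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "hashes": {p.name: _sha256(p) for p in artifacts if p.name != "manifest.json"},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out
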