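# ddepi — cohort epidemiology of Dupuytren disease

`ddepi` is a tested, reusable implementation of a population-based cohort
analysis of Dupuytren disease (DD): how often the disease is diagnosed, how
often it is first treated surgically, and how likely a newly diagnosed
patient is to ever undergo surgery. It is aimed at epidemiologists and
health-services researchers working with linked primary-care/hospital event
tables (a CPRD/HES-like structure), and at methodologists who want a fully
synthetic, ground-truthed testbed for this class of analysis.

Because real UK primary-care and hospital databases are access-controlled,
the package ships a synthetic-cohort generator that emulates the statistical
structure such studies assume — age- and sex-specific diagnosis incidence,
proportional-hazards time from diagnosis to surgery, life-table mortality,
registration churn, and the record defects (missing gender, missing death
dates, diagnosis-equals-treatment artefacts, revision-only surgical
histories) that exclusion cascades must handle. Every downstream estimate
can therefore be checked against a known truth.

## What it computes

- **Cohort construction** — an ordered exclusion cascade with a
  flowchart-style report, year-specific at-risk cohorts, and the diagnosed
  cohort for time-to-surgery analyses (revision-only patients removed,
  pre-linkage diagnoses removed, 3-year run-in).
- **Point prevalence** of diagnosed DD on a reference date (Wilson 99% CI)
  and **incidence** of diagnosis and of first surgery per 1000 person-years
  (exact Poisson 99% CI), crude and **directly age-standardized**.
- **Observed risk** — Kaplan–Meier 1−S(t) curves by gender and age-quartile,
  and Cox proportional-hazards ratios (Efron ties) for male gender and age
  at diagnosis.
- **Parametric survival models** for the diagnosis→surgery transition:
  exponential, Weibull, log-logistic, log-normal, and flexible parametric
  spline models with 1–3 internal knots,

  log H(t | x) = s(log t; γ) + β₁·I(male) + β₂·age_dx,

  where s is a natural cubic spline (boundary knots at the extreme
  uncensored log event times, internal knots at quantiles), fitted by
  maximum likelihood with right censoring; AIC ranking plus an
  extrapolation report for model selection.
- **Lifetime risk** of first surgery via an illness–death multistate Markov
  model: a cohort enters the DD state at diagnosis; each monthly cycle it
  competes an age-specific death hazard h_d = −ln(1−qx) from a national
  life table against the fitted surgery hazard h_s, with the exact
  competing-exponential within-cycle allocation
  p_surgery = h_s/(h_s+h_d)·(1−e^−(h_s+h_d)Δ). Lifetime risk is the
  terminal occupancy of the surgery state; 99% CIs come from a
  nonparametric bootstrap of the diagnosed cohort.

## Worked example

```python
from ddepi import (simulate_diagnosed_cohort, fit_proportional_hazards,
                   fit_parametric, run_markov, PatientProfile)
from ddepi.lifetable import packaged_life_table

# 20,000 diagnosed patients; true male HR 2.0, true age HR 1.011/yr
records, truth = simulate_diagnosed_cohort(20_000, seed=7)

cox = fit_proportional_hazards(records)
print(f"HR male = {cox.hr_male:.3f} (95% CI {cox.ci_male[0]:.3f}-{cox.ci_male[1]:.3f})")
print(f"HR per year of age = {cox.hr_age:.3f} (95% CI {cox.ci_age[0]:.3f}-{cox.ci_age[1]:.3f})")

fit = fit_parametric(records, "spline-3")      # flexible parametric model
life = packaged_life_table()                   # synthetic Gompertz life table
for gender in ("male", "female"):
    r = run_markov(fit, life, PatientProfile(gender, 65))
    print(f"lifetime risk, {gender} diagnosed at 65: {100*r.lifetime_risk:.1f}%")
```

Output:

```
HR male = 1.978 (95% CI 1.802-2.171)
HR per year of age = 1.014 (95% CI 1.010-1.017)
lifetime risk, male diagnosed at 65: 22.9%
lifetime risk, female diagnosed at 65: 13.4%
```

The Cox fit recovers the generator's truth (male hazard ratio 2, age hazard
ratio 1.011 per year) within sampling error, and the Markov model turns the
fitted surgery model plus life-table mortality into lifetime risks: a man
diagnosed at 65 has roughly one-in-four odds of ever being operated, a
woman roughly one-in-seven — close to twice the risk in men, as the
covariate effect dictates.

The same steps run from the shell:

```bash
ddepi simulate --out sim --seed 4 --n 120000
ddepi build-cohort --in sim --out built
ddepi rates --cohort built --outcome diagnosis --years 2000:2013 --standardize --out rates.csv
ddepi fit-survival --cohort sim --family weibull --out fit.json
ddepi lifetime-risk --fit fit.json --ages 40:90:5 --out lifetime.csv
ddepi run-all --seed 5 --out full_run     # entire pipeline + manifest
```

## Layout

| module | contents |
| --- | --- |
| `ddepi.simulate` | synthetic cohort generator, cohort CSV I/O |
| `ddepi.lifetable` | life-table loading/validation, synthetic Gompertz fixture |
| `ddepi.filters` | exclusion cascades, year-specific at-risk cohorts |
| `ddepi.rates` | prevalence, incidence, direct standardization |
| `ddepi.survival` | KM, Cox, parametric/spline survival models |
| `ddepi.markov` | illness–death model, bootstrap, profile sweeps |
| `ddepi.report` / `ddepi.cli` | pipeline orchestration, `ddepi` console script |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
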