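# Methods

This note documents the models implemented in `ddepi`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions that matter when reproducing results.

## Study design being modelled

The package reimplements, over synthetic data, a dynamic-cohort design:
a registered primary-care population observed over a calendar window
(default 1995-01-01 to 2013-12-31), with GP-recorded DD diagnoses and
hospital-recorded surgical procedures linked at the subject level.
Hospital procedure coverage begins later than primary care (default
1997) and only for English practices, and the first three years of
procedure coverage are treated as a run-in, so incidence series and the
diagnosed analysis cohort start in 2000. A run-in is needed because
early "incident" codes are partly a backlog of prevalent disease being
recorded for the first time.

## Synthetic cohort generator (`ddepi.simulate`)

One integer seed drives every draw. Latent times are simulated in
continuous time by inversion over piecewise-constant yearly hazards and
floored to day resolution (EHR dates are daily). Death and transfer-out
compete with diagnosis and surgery by taking the earliest latent time.
Subjects are assigned birth year only (as in primary-care extracts) and
are treated as born on January 1, which makes ages exact at calendar
year boundaries; all age arithmetic downstream uses the same convention.

Default parameters, with rationale:

| parameter | default | why |
| --- | --- | --- |
| `n_subjects` | 50,000 | desk-scale; analyses in the repo use 150,000 where rate stability matters |
| `male_fraction` | 0.49 | UK adult population mix |
| `birth_year_range` | 1913–1995 | at-risk ages span 18–100 across the window |
| `diagnosis_hazard_base` | 9.3e-4 /yr | calibrated once so pooled 2000–2013 all-ages diagnosis incidence is ≈0.6 per 1000 person-years, the magnitude reported for UK primary care |
| `diagnosis_age_peak`, width | 70 yr, 15 yr | log-quadratic age effect: the simplest form producing the peaked age–incidence curve seen in this disease |
| `diagnosis_male_rate_ratio` | 2.0 | male incidence roughly double female incidence |
| `surgery_baseline` | Weibull(shape 0.5, scale 4227 yr) | decreasing hazard: treatment risk is front-loaded in the first years after diagnosis; scale calibrated once so a woman diagnosed at 65 has a true lifetime surgery risk of ≈13% under the fixture life table |
| `surgery_log_hr_male` | ln 2 | men about twice as likely to be operated once diagnosed |
| `surgery_log_hr_age_per_year` | 0.011 | hazard ratio 1.011 per year of age at diagnosis |
| `annual_registration_exit_prob` | 0.02 | registration churn; geometric exit |
| defect probabilities | 0 | exclusion-triggering defects are opt-in so that a clean simulation passes the cascade untouched |

With these defaults the implied fractions come out internally
consistent: ≈0.8% point prevalence in 2013, ≈13% of diagnosed patients
surgically treated within follow-up, and true lifetime risks at
diagnosis age 65 of ≈22.5% (men) and 13% (women), a ratio of ≈1.73.
An exponential surgery baseline cannot reach that ratio: with a male
log-HR of ln 2 the female longevity advantage caps the male:female
lifetime-risk ratio at ≈1.72 even as rates go to zero, and depletion
pushes it lower at realistic rates. The decreasing Weibull concentrates
surgery risk early — where mortality competition is weakest — which is
both what the observed-risk curves show and what restores the
near-twofold ratio.

`simulate_diagnosed_cohort` is a shortcut generator for the
time-to-surgery layer alone (gender mix 64.6% male, age at diagnosis
normal with mean 63 and SD 11 clipped to [18, 95], administrative
censoring uniform on 1–14 years, mirroring a diagnosis date spread over
a fixed calendar window). It exists so survival-model studies at large
n do not pay for the population layer.

What the generator does **not** emulate: secular trends (incidence is
constant over calendar time, so yearly series are flat apart from
population aging, unlike the rising real-world series), coding-system
granularity (three event types replace Read/OPCS-4 lists), laterality
and recurrence dynamics, practice-level joining/leaving beyond a single
exit probability, comorbidity–disease dependence (diabetes, epilepsy
and hypercholesterolemia are independent flags used only for
table-one-style summaries), and DD-specific excess mortality. Passing
tests therefore demonstrate correctness of the estimators and engine on
data satisfying the model's assumptions, not robustness to real-data
violations of them.

## Life tables (`ddepi.lifetable`)

CSV schema `sex,age,qx` with contiguous ages per sex from ≤18 to ≥100.
The packaged fixture is synthetic Gompertz, qx = min(1, A·e^(0.09·age))
with A chosen so life expectancy at birth is ≈79 (men) and ≈83 (women);
the terminal row (age 100) carries qx = 1 so cohort computations close.
Users may substitute real national period tables with the same schema.
The qx→hazard conversion h = −ln(1−qx) assumes a constant hazard within
the year of age — the standard actuarial approximation. Ages above the
tabulated maximum are clamped to the terminal row with a warning. A
single period table is used throughout (no calendar-year-specific
mortality).

## Exclusion cascades (`ddepi.filters`)

Base cascade order: no recorded gender → died or left strictly before
the study start (ties on the start date retained) → never aged 18–109
during the window → death recorded but date missing → diagnosis date
missing or equal to a treatment date. The order within the
missing-data rules is a documented convention; per-step counts depend
on it, the final cohort only through subjects violating several rules
at once. Diagnosed-cohort cascade: undiagnosed → no hospital linkage
(devolved-nation practices) → revision-only surgical history →
diagnosed before hospital coverage → diagnosed during the run-in.
The run-in is anchored at the hospital-coverage start (1997 + 3 years =
2000), matching the presented-from year of the study design.

Person-time conventions: closed day intervals, person-years =
days/365.25 (leap-year neutral); a subject enters a year's at-risk set
at the latest of January 1, registration start and the 18th birthday,
and exits at the earliest of outcome, death, deregistration and
December 31. For first-surgery incidence the default denominator is the
full eligible population without prior surgery (`denominator=
"population"`), so diagnosis and surgery incidence share a scale; the
diagnosed-only denominator is available as a switch.

## Rates (`ddepi.rates`)

Prevalence: cases among registered, alive, age-eligible subjects on the
reference date; Wilson interval. Incidence: exact Poisson (Garwood)
interval for the count, scaled by person-years. Direct standardization:
Σ wᵢ·rateᵢ with variance Σ wᵢ²·countᵢ/PYᵢ² and a normal interval
truncated at zero. These interval methods are standard epidemiological
practice where a study states only the confidence level. The default
standard population is the pooled person-year age distribution of the
year-specific cohorts (internal standard: makes the yearly series
comparable without an external reference); any weight vector — e.g. the
European Standard Population — can be supplied instead. Default age
bands are 18–24, 25–34, …, 75–84, 85+. Gender is a stratifier only;
no gender standardization is applied. Empty denominators yield
estimates flagged `undefined`, never silent zeros.

## Survival models (`ddepi.survival`)

Kaplan–Meier curves and the Cox model (Efron tie handling, Wald CIs)
are delegated to lifelines. Age quartiles for the observed-risk curves
are computed from the analyzed cohort itself.

The flexible parametric family models the log cumulative hazard as a
restricted (natural) cubic spline in log time plus a proportional-
hazards linear predictor in male gender and age at diagnosis. The
proportional-hazards scale (rather than proportional odds or probit)
was chosen because hazard ratios are the reported effect measure and
the Markov engine consumes hazards. Exponential (slope fixed at 1) and
Weibull (straight line) are the 0-knot members of the same framework;
spline-k adds k internal knots at equally spaced quantiles of the
uncensored log event times, with boundary knots at their extremes — the
standard flexible-parametric convention when only knot counts are
specified. Log-logistic and log-normal are accelerated-failure-time
models fitted by lifelines; they join the AIC comparison but have no
proportional-hazards form. ("Log-linear" in older distribution lists is
read as log-logistic; it is not a standard survival family name.)

Fitting: maximum likelihood with right censoring, analytic gradients,
L-BFGS-B, warm start from the closed-form exponential rate (and from
the Weibull fit for spline families), up to five perturbed restarts;
a quadratic penalty keeps the spline's log-time slope positive at event
times (negative slope would mean negative hazard). The variance matrix
is the inverse numerical Hessian of the negative log-likelihood.
Model selection ranks by AIC with ties broken by canonical family
order, and emits an extrapolation table (cumulative risk to the horizon
per candidate, with the observed-time KM overlay) because AIC alone
cannot judge extrapolation plausibility; a configured override can pin
the chosen family.

## Markov lifetime-risk engine (`ddepi.markov`)

Three states: DD (entry, at diagnosis), first surgery (absorbing),
death (absorbing). Cycle length defaults to one month. Per cycle the
surgery hazard is recovered from the fitted model's conditional event
probability over the cycle, 1 − S(t+Δ|x)/S(t|x), so DD-state survival
telescopes exactly to the fitted S(t); the death hazard is −ln(1−qx) at
the current age (age at diagnosis + elapsed time, floored to whole
years, as life tables are annual). Within-cycle competition uses the
exact two-exponential allocation, so no half-cycle correction is
needed, occupancy is conserved to 1e−10 by construction, and with zero
mortality the terminal risk equals 1 − S(horizon) to machine precision.
The horizon is age 100 (the fixture table's ceiling); survivors beyond
it accrue no further surgery risk — the residual DD-state mass there is
a few percent and real qx beyond 100 is unstable. Lifetime risk is the
terminal surgery-state occupancy.

Uncertainty: nonparametric bootstrap of the diagnosed cohort — refit
the chosen family per resample (knots re-placed per resample), rerun
the engine per profile, percentile interval (default 99%, default 200
replicates; analyses in this repo use 100 where runtime matters). The
full-data fit provides the point estimate; a run fails if more than 5%
of replicate fits do not converge. Calendar year of diagnosis is not a
model covariate (no trend in the treated proportion by diagnosis year
under the generator, matching the design being mirrored).

## Numerical conventions and edge cases

- Convergence: `ftol` 1e−12 / `gtol` 1e−8 on the penalized negative
  log-likelihood; spline likelihoods can be flat, hence restarts.
- `S(t0) = 0` in a conditional probability returns 1 with a warning;
  hazards from probabilities are capped at 40/yr (e.g. terminal qx = 1).
- Degenerate Markov horizons (diagnosis age ≥ max age) return risk 0.
- Zero-event strata: KM curves flat at 0 and flagged; incidence 0 with
  a positive upper Garwood bound; empty denominators flagged undefined.
- Exclusion rules treat defects as removals, never errors; malformed
  CSV input (bad dates, unknown event types) fails naming the row.
- All percentages in display tables are 100·part/whole rounded to one
  decimal; underlying CSVs keep full precision.

## Problem sizes used in the shipped analyses

Population-level quantities (prevalence, standardized incidence) are
computed on 150,000-subject simulations — large enough that yearly
standardized rates are stable to a few percent. Survival-model and
lifetime-risk studies use 20,000 diagnosed subjects (≈2,500 surgery
events), the scale at which the spline fit's survival curve tracks the
generating truth within 0.02 everywhere and hazard ratios are recovered
within a few percent. Bootstrap intervals use 100 replicates in the
shipped scripts.

## Known limitations

- The synthetic world is stationary; rising secular trends in incidence
  are not reproduced, only the cross-sectional structure.
- Lifetime risks inherit the fixture life table; with real national
  tables the absolute risks will shift (and DD patients' reported
  excess mortality would shift them further down).
- The spline model extrapolates beyond observed follow-up by design;
  the extrapolation report exists precisely because that step is not
  testable against data.
- Left truncation, time-varying covariates, cure fractions, and
  post-surgery (recurrence/revision) states are out of scope.
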