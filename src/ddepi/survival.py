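"""Time from DD diagnosis to first surgery: KM, Cox, and parametric models.

Three layers:

* **Observed risk** — Kaplan–Meier 1−survival curves (with Greenwood
  intervals) stratified by gender or by quartile of age at diagnosis,
  and a semi-parametric Cox proportional-hazards fit (Efron ties) for
  the male and per-year-of-age hazard ratios.

* **Parametric families** — exponential, Weibull, log-logistic,
  log-normal, and flexible parametric (spline) models with 1–3 internal
  knots.  The spline family models the log cumulative hazard as a
  natural (restricted) cubic spline in log time plus a linear predictor
  on the proportional-hazards scale:

      log H(t | x) = s(log t; gamma) + beta_male * I(male)
                                     + beta_age * age_at_diagnosis

  Internal knots sit at equally spaced quantiles of the uncensored log
  event times, boundary knots at their extremes.  With no internal
  knots the spline is a straight line in log time and the model *is*
  Weibull PH; fixing the slope at one gives the exponential model.
  Maximum likelihood with right censoring, analytic gradients, L-BFGS
  with perturbed restarts (spline likelihoods can be flat).

* **Model selection and transition probabilities** — AIC ranking with
  an extrapolation report (fitted cumulative risk out to a horizon
  against the KM curve over observed time), and the per-cycle
  conditional event probability 1 − S(t1|x)/S(t0|x) consumed by the
  multistate Markov engine.

The log-logistic and log-normal families are accelerated-failure-time
models delegated to lifelines; they participate in AIC comparison but
are not on the PH scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import LogLogisticAFTFitter, LogNormalAFTFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal",
            "spline-1", "spline-2", "spline-3")

_SPLINE_FAMILIES = {"exponential": 0, "weibull": 0, "spline-1": 1, "spline-2": 2, "spline-3": 3}


class ConvergenceError(RuntimeError):
    pass


def _gender_age(profile) -> tuple[str, float]:
    if hasattr(profile, "gender"):
        return profile.gender, float(profile.age_at_diagnosis)
    g, a = profile
    return g, float(a)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    need = {"time", "event", "age_at_diagnosis", "gender"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if (records["time"] <= 0).any():
        raise ValueError("nonpositive follow-up time in records")
    return records


# ---------------------------------------------------------------------------
# restricted cubic spline basis on log time

def _rcs(z: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline terms v_j(z) and derivatives for internal knots.

    ``knots`` holds [boundary_min, internal..., boundary_max].  Terms are
    scaled by (k_max - k_min)^2 so coefficients are O(1).
    """
    kmin, kmax = knots[0], knots[-1]
    scale = (kmax - kmin) ** 2
    z = np.asarray(z, dtype=float)[:, None]

    def cube(x):
        return np.maximum(x, 0.0) ** 3

    def dcube(x):
        return 3.0 * np.maximum(x, 0.0) ** 2

    kj = knots[1:-1][None, :]
    lam = (kmax - knots[1:-1]) / (kmax - kmin)
    v = (cube(z - kj) - lam * cube(z - kmin) - (1 - lam) * cube(z - kmax)) / scale
    vp = (dcube(z - kj) - lam * dcube(z - kmin) - (1 - lam) * dcube(z - kmax)) / scale
    return v, vp


def _spline_design(z: np.ndarray, family: str, knots: np.ndarray | None):
    """Return (B, Bp, offset, offset_deriv): eta = B@gamma + offset + X@beta."""
    n = len(z)
    one = np.ones((n, 1))
    zero = np.zeros((n, 1))
    zc = z[:, None]
    if family == "exponential":
        return one, zero, z, 1.0
    if family == "weibull":
        return np.hstack([one, zc]), np.hstack([zero, one]), 0.0, 0.0
    v, vp = _rcs(z, knots)
    return np.hstack([one, zc, v]), np.hstack([zero, one, vp]), 0.0, 0.0


def default_knots(times: np.ndarray, events: np.ndarray, n_internal: int) -> np.ndarray:
    """Boundary knots at min/max uncensored log times, internal knots at
    equally spaced quantiles of the uncensored log event times."""
    lt = np.log(np.asarray(times, float)[np.asarray(events, bool)])
    if lt.size < 2:
        raise ValueError("need at least two uncensored events to place knots")
    qs = np.linspace(0, 1, n_internal + 2)
    return np.unique(np.quantile(lt, qs))


@dataclass
class SplineSurvivalFit:
    """A fitted log-cumulative-hazard model (exponential / Weibull / spline).

    ``gamma`` are the baseline spline coefficients, ``beta`` the log
    hazard ratios ``[male, per year of age at diagnosis]``.
    """

    family: str
    gamma: np.ndarray
    beta: np.ndarray
    knots: np.ndarray | None
    loglik: float
    n: int
    n_events: int
    vcov: np.ndarray | None = None
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.gamma) + len(self.beta)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def log_hr_male(self) -> float:
        return float(self.beta[0])

    @property
    def log_hr_age(self) -> float:
        return float(self.beta[1])

    def _linear_predictor(self, profile) -> float:
        gender, age = _gender_age(profile)
        return float(self.beta[0] * (gender == "male") + self.beta[1] * age)

    def log_cumulative_hazard(self, t, profile) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, -np.inf)
        pos = t > 0
        if pos.any():
            z = np.log(t[pos])
            b, _, off, _ = _spline_design(z, self.family, self.knots)
            out[pos] = b @ self.gamma + off + self._linear_predictor(profile)
        return out

    def cumulative_hazard(self, t, profile) -> np.ndarray:
        return np.exp(np.minimum(self.log_cumulative_hazard(t, profile), 500.0))

    def survival(self, t, profile) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(t, profile))

    def hazard(self, t, profile) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        z = np.log(np.maximum(t, 1e-300))
        _, bp, _, offd = _spline_design(z, self.family, self.knots)
        sprime = bp @ self.gamma + offd
        return self.cumulative_hazard(t, profile) * sprime / t

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "gamma": list(map(float, self.gamma)),
            "beta": list(map(float, self.beta)),
            "knots": None if self.knots is None else list(map(float, self.knots)),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSurvivalFit":
        return cls(
            family=d["family"],
            gamma=np.asarray(d["gamma"], float),
            beta=np.asarray(d["beta"], float),
            knots=None if d["knots"] is None else np.asarray(d["knots"], float),
            loglik=float(d["loglik"]),
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            vcov=None if d.get("vcov") is None else np.asarray(d["vcov"], float),
        )


@dataclass
class AFTSurvivalFit:
    """Log-logistic or log-normal AFT fit, wrapped for a common interface."""

    family: str
    fitter: object
    loglik: float
    n: int
    n_events: int

    @property
    def aic(self) -> float:
        return float(self.fitter.AIC_)

    @property
    def n_params(self) -> int:
        return len(self.fitter.params_)

    def survival(self, t, profile) -> np.ndarray:
        gender, age = _gender_age(profile)
        row = pd.DataFrame({"male": [1.0 * (gender == "male")], "age_at_diagnosis": [age]})
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tq = np.maximum(t, 1e-12)
        s = self.fitter.predict_survival_function(row, times=tq).to_numpy()[:, 0]
        return np.where(t <= 0, 1.0, s)

    def hazard(self, t, profile) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        eps = 1e-6
        s0 = self.survival(t, profile)
        s1 = self.survival(t + eps, profile)
        return np.clip(-(np.log(np.maximum(s1, 1e-300)) - np.log(np.maximum(s0, 1e-300))) / eps,
                       0.0, None)


def _negloglik_and_grad(theta, b, bp, x, z, delta, off, offd):
    ng = b.shape[1]
    g, be = theta[:ng], theta[ng:]
    eta = b @ g + off + x @ be
    eta = np.clip(eta, -500, 500)
    h_cum = np.exp(eta)
    sp = bp @ g + offd
    sp_ev = sp[delta]
    bad = sp_ev <= 0
    sp_safe = np.where(bad, 1e-10, sp_ev)

    ll = np.sum(eta[delta] + np.log(sp_safe) - z[delta]) - np.sum(h_cum)
    penalty = 1e4 * np.sum(np.minimum(sp_ev, 0.0) ** 2)

    grad_g = (b[delta] + bp[delta] / sp_safe[:, None]).sum(axis=0) - h_cum @ b
    grad_b = x[delta].sum(axis=0) - h_cum @ x
    pen_grad_g = 1e4 * 2.0 * (np.minimum(sp_ev, 0.0)[:, None] * bp[delta]).sum(axis=0)
    return -(ll) + penalty, np.concatenate([-(grad_g) + pen_grad_g, -grad_b])


def _numeric_hessian(fun, theta, eps=1e-5):
    k = len(theta)
    hess = np.zeros((k, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        _, gp = fun(tp)
        _, gm = fun(tm)
        hess[:, i] = (gp - gm) / (2 * eps)
    return (hess + hess.T) / 2


def fit_parametric(
    records: pd.DataFrame,
    family: str,
    knots: np.ndarray | None = None,
    min_events: int = 30,
    max_restarts: int = 5,
):
    """Maximum-likelihood fit of one parametric family with right censoring.

    Covariates are always male gender and age at diagnosis.  For spline
    families, ``knots`` overrides the default quantile placement.
    """
    records = _check_records(records)
    t = records["time"].to_numpy(float)
    delta = records["event"].to_numpy(bool)
    if delta.sum() < min_events:
        raise ValueError(f"need at least {min_events} events, got {int(delta.sum())}")
    x = np.column_stack(
        [(records["gender"] == "male").to_numpy(float), records["age_at_diagnosis"].to_numpy(float)]
    )
    if family in ("loglogistic", "lognormal"):
        return _fit_aft(records, family)
    if family not in _SPLINE_FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")

    n_internal = _SPLINE_FAMILIES[family]
    if family in ("exponential", "weibull"):
        knots = None
    elif knots is None:
        knots = default_knots(t, delta, n_internal)

    z = np.log(t)
    b, bp, off, offd = _spline_design(z, family, knots)
    off = off if np.ndim(off) else np.full(len(z), float(off))
    fun = lambda th: _negloglik_and_grad(th, b, bp, x, z, delta, off, offd)

    # init from the exponential closed form: rate = events / total time
    lam = delta.sum() / t.sum()
    g0 = np.zeros(b.shape[1])
    g0[0] = np.log(lam)
    if b.shape[1] > 1:
        g0[1] = 1.0
    theta0 = np.concatenate([g0, np.zeros(2)])
    if family not in ("exponential",):
        # warm start the betas (and level) from a Weibull fit when available
        try:
            wb = fit_parametric(records, "weibull", min_events=min_events) \
                if family != "weibull" else None
        except Exception:
            wb = None
        if wb is not None:
            theta0[0] = wb.gamma[0]
            theta0[1] = wb.gamma[1]
            theta0[-2:] = wb.beta

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.2, len(theta0))
        res = optimize.minimize(fun, start, jac=True, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun else best
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            f"{family} fit failed after {max_restarts} restarts; last status: "
            f"{getattr(best, 'message', 'n/a')}"
        )
    theta = best.x
    ng = b.shape[1]
    try:
        hess = _numeric_hessian(fun, theta)
        vcov = np.linalg.pinv(hess)
    except Exception:
        vcov = None
    nll, _ = fun(theta)
    return SplineSurvivalFit(
        family=family,
        gamma=theta[:ng],
        beta=theta[ng:],
        knots=knots,
        loglik=-float(nll),
        n=len(t),
        n_events=int(delta.sum()),
        vcov=vcov,
        converged=bool(best.success),
    )


def _fit_aft(records: pd.DataFrame, family: str) -> AFTSurvivalFit:
    df = pd.DataFrame(
        {
            "time": records["time"].to_numpy(float),
            "event": records["event"].to_numpy(bool),
            "male": (records["gender"] == "male").to_numpy(float),
            "age_at_diagnosis": records["age_at_diagnosis"].to_numpy(float),
        }
    )
    fitter = LogLogisticAFTFitter() if family == "loglogistic" else LogNormalAFTFitter()
    fitter.fit(df, duration_col="time", event_col="event")
    return AFTSurvivalFit(
        family=family,
        fitter=fitter,
        loglik=float(fitter.log_likelihood_),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


# ---------------------------------------------------------------------------
# observed risk

def age_quartile_labels(records: pd.DataFrame) -> tuple[pd.Series, np.ndarray]:
    """Quartile bands of age at diagnosis, cut points from the cohort itself."""
    cuts = np.quantile(records["age_at_diagnosis"], [0.25, 0.5, 0.75])
    labels = pd.cut(
        records["age_at_diagnosis"],
        bins=[-np.inf, *cuts, np.inf],
        labels=[f"Q{i + 1}" for i in range(4)],
    )
    return labels.astype(str), cuts


def km_one_minus_survival(
    records: pd.DataFrame, by: str | None = None, level: float = 0.95
) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier cumulative incidence 1−S(t) per stratum.

    ``by`` is None (one overall curve), "gender", or "age_quartile"
    (quartiles of age at diagnosis computed from these records).
    Returns per-stratum frames with columns time, n_risk, n_event,
    one_minus_s, ci_low, ci_high (Greenwood / log-log intervals).  A
    stratum with no events yields a flat curve flagged via
    ``frame.attrs["all_censored"]``.
    """
    records = _check_records(records)
    if len(records) == 0:
        raise ValueError("no records")
    if by is None:
        groups = {"all": records}
    elif by == "gender":
        groups = {g: sub for g, sub in records.groupby("gender")}
    elif by == "age_quartile":
        labels, _ = age_quartile_labels(records)
        groups = {q: sub for q, sub in records.groupby(labels.to_numpy())}
    else:
        raise ValueError(f"unknown stratifier {by!r}")

    out = {}
    for name, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], alpha=1 - level)
        et = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        ci = kmf.confidence_interval_
        frame = pd.DataFrame(
            {
                "time": et.index.to_numpy(float),
                "n_risk": et["at_risk"].to_numpy(int),
                "n_event": et["observed"].to_numpy(int),
                "one_minus_s": 1.0 - surv.reindex(et.index).to_numpy(float),
                "ci_low": 1.0 - ci.iloc[:, 1].reindex(et.index).to_numpy(float),
                "ci_high": 1.0 - ci.iloc[:, 0].reindex(et.index).to_numpy(float),
            }
        )
        frame.attrs["all_censored"] = int(et["observed"].sum()) == 0
        out[str(name)] = frame
    return out


@dataclass
class CoxPHResult:
    log_hr_male: float
    log_hr_age: float
    se_male: float
    se_age: float
    ci_male: tuple[float, float]  # on the HR scale, 95%
    ci_age: tuple[float, float]
    summary: pd.DataFrame

    @property
    def hr_male(self) -> float:
        return float(np.exp(self.log_hr_male))

    @property
    def hr_age(self) -> float:
        return float(np.exp(self.log_hr_age))


def fit_proportional_hazards(records: pd.DataFrame, level: float = 0.95) -> CoxPHResult:
    """Cox PH fit (Efron tie handling) of male gender and age at diagnosis."""
    records = _check_records(records)
    if records["gender"].nunique() < 2:
        raise ValueError("both genders must be present for the Cox fit")
    df = pd.DataFrame(
        {
            "time": records["time"],
            "event": records["event"].astype(bool),
            "male": (records["gender"] == "male").astype(float),
            "age_at_diagnosis": records["age_at_diagnosis"].astype(float),
        }
    )
    cph = CoxPHFitter(alpha=1 - level)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except _LLConvergenceError as err:
        raise ConvergenceError(
            f"Cox partial likelihood did not converge (possible complete "
            f"separation): {err}"
        ) from err
    s = cph.summary
    lo, hi = s.filter(like="coef lower").columns[0], s.filter(like="coef upper").columns[0]
    return CoxPHResult(
        log_hr_male=float(s.loc["male", "coef"]),
        log_hr_age=float(s.loc["age_at_diagnosis", "coef"]),
        se_male=float(s.loc["male", "se(coef)"]),
        se_age=float(s.loc["age_at_diagnosis", "se(coef)"]),
        ci_male=(float(np.exp(s.loc["male", lo])), float(np.exp(s.loc["male", hi]))),
        ci_age=(float(np.exp(s.loc["age_at_diagnosis", lo])),
                float(np.exp(s.loc["age_at_diagnosis", hi]))),
        summary=s,
    )


# ---------------------------------------------------------------------------
# model selection and transition probabilities

@dataclass
class ModelSelection:
    best: object
    ranking: pd.DataFrame          # family, loglik, n_params, aic, rank
    extrapolation: pd.DataFrame    # family, time, one_minus_s
    km: pd.DataFrame               # observed-time KM overlay


def select_model(
    fits: list,
    records: pd.DataFrame | None = None,
    horizon: float = 50.0,
    profile=("male", 65.0),
    override: str | None = None,
) -> ModelSelection:
    """Rank candidate fits by AIC and build an extrapolation report.

    Ties and ordering fall back on the canonical family order.  The
    report tabulates each candidate's cumulative risk out to ``horizon``
    years for ``profile`` so that extrapolation plausibility can be
    inspected alongside the observed-time KM curve; the AIC-best fit is
    returned unless ``override`` names a family.
    """
    if len(fits) < 2 and override is None:
        raise ValueError("need at least two candidate fits to select among")
    order = {f: i for i, f in enumerate(FAMILIES)}
    ranked = sorted(fits, key=lambda f: (f.aic, order.get(f.family, 99)))
    ranking = pd.DataFrame(
        {
            "family": [f.family for f in ranked],
            "loglik": [f.loglik for f in ranked],
            "n_params": [f.n_params for f in ranked],
            "aic": [f.aic for f in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
    times = np.linspace(0.0, horizon, 201)
    rows = []
    for f in fits:
        s = f.survival(times, profile)
        rows.append(pd.DataFrame({"family": f.family, "time": times, "one_minus_s": 1 - s}))
    extrap = pd.concat(rows, ignore_index=True)
    if records is not None:
        km = km_one_minus_survival(records)["all"]
    else:
        km = pd.DataFrame(columns=["time", "n_risk", "n_event", "one_minus_s",
                                   "ci_low", "ci_high"])
    best = ranked[0]
    if override is not None:
        match = [f for f in fits if f.family == override]
        if not match:
            raise ValueError(f"override family {override!r} not among the fits")
        best = match[0]
    return ModelSelection(best=best, ranking=ranking, extrapolation=extrap, km=km)


def conditional_surgery_probability(fit, profile, t0, t1) -> np.ndarray | float:
    """Per-cycle conditional event probability 1 − S(t1|x)/S(t0|x).

    Accepts scalars or arrays (broadcast elementwise); S(t0)=0 yields 1
    by convention, with a warning.
    """
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t0 < 0) or np.any(t1 < t0):
        raise ValueError("need 0 <= t0 <= t1")
    s0 = fit.survival(np.atleast_1d(t0), profile)
    s1 = fit.survival(np.atleast_1d(t1), profile)
    dead = s0 <= 0.0
    if dead.any():
        warnings.warn("S(t0) = 0: conditional event probability set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(dead, 1.0, 1.0 - s1 / np.where(dead, 1.0, s0))
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if p.size == 1 and np.ndim(t0) == 0 else p
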