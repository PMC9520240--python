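"""Parametric survival machinery for the microsimulation.

Weibull accelerated-failure-time (AFT) models drive type 2 diabetes (T2D)
onset (with and without the polygenic risk score as a covariate) and the
onset of T2D complications; a sex- and age-specific life table drives
all-cause mortality, adjusted in the diseased states by published hazard
ratios.

Parameterization
----------------
The AFT convention used throughout is

    S(t | x) = exp(-(t / lam(x))**k),   lam(x) = exp(intercept + x . beta),
    k = 1 / scale

where ``scale`` is the usual AFT log-time scale parameter (``sigma``), so
``k`` is the Weibull shape.  ``k = 1`` reduces to the exponential model.
Covariates accelerate or decelerate event time; a negative coefficient on
log-lambda shortens time to event, i.e. increases risk.

Annual transition probabilities for the 1-year-cycle state-transition model
are conditional probabilities ``1 - S(t+1)/S(t)``; their complements
telescope back to the survival function exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeibullAFTModel",
    "LifeTable",
    "MortalityAdjustment",
    "survival_at",
    "risk_over",
    "annual_event_prob",
    "apply_hazard_ratio",
    "mortality_prob",
    "fit_aft",
    "compare_families",
    "make_synthetic_life_table",
    "AFT_FAMILIES",
]

AFT_FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")


@dataclass(frozen=True)
class WeibullAFTModel:
    """Weibull AFT model: ``S(t|x) = exp(-(t/lam)^k)`` with
    ``lam = exp(intercept + x.beta)`` and shape ``k = 1/scale``."""

    intercept: float
    coefficients: Mapping[str, float]
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        names = list(self.coefficients)
        if len(names) != len(set(names)):
            raise ValueError("covariate names must be unique")

    @property
    def shape(self) -> float:
        """Weibull shape parameter ``k = 1/scale``."""
        return 1.0 / self.scale

    def linear_predictor(self, covariates: Mapping[str, object]) -> np.ndarray:
        """``intercept + x . beta`` (log of the AFT scale lambda).

        Covariate values may be scalars or aligned arrays; missing
        covariates raise a ``KeyError`` naming the offender.
        """
        lp = np.asarray(self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            if name not in covariates:
                raise KeyError(f"missing covariate {name!r}")
            lp = lp + beta * np.asarray(covariates[name], dtype=float)
        return lp

    def lam(self, covariates: Mapping[str, object]) -> np.ndarray:
        return np.exp(self.linear_predictor(covariates))

    def with_coefficient(self, name: str, value: float) -> "WeibullAFTModel":
        coefs = dict(self.coefficients)
        coefs[name] = value
        return WeibullAFTModel(self.intercept, coefs, self.scale)

    def to_dict(self) -> dict:
        return {
            "parameterization": "aft_log_lambda",
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeibullAFTModel":
        tag = d.get("parameterization", "aft_log_lambda")
        if tag != "aft_log_lambda":
            raise ValueError(f"unknown parameterization tag {tag!r}")
        return cls(float(d["intercept"]), dict(d["coefficients"]), float(d["scale"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "WeibullAFTModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def survival_at(model: WeibullAFTModel, covariates: Mapping, t) -> np.ndarray:
    """Survival probability ``S(t | x)``; vectorized over ``t`` and covariates."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam = model.lam(covariates)
    return np.exp(-((t / lam) ** model.shape))


def risk_over(model: WeibullAFTModel, covariates: Mapping, horizon) -> np.ndarray:
    """Cumulative event risk ``1 - S(horizon | x)``."""
    return 1.0 - survival_at(model, covariates, horizon)


def annual_event_prob(model: WeibullAFTModel, covariates: Mapping, t) -> np.ndarray:
    """Probability of the event in cycle ``(t, t+1]`` given event-free at ``t``.

    Computed as ``1 - S(t+1)/S(t)``; the complements multiply back to the
    survival function exactly (telescoping identity).
    """
    t = np.asarray(t, dtype=float)
    s_t = survival_at(model, covariates, t)
    if np.any(s_t <= 0.0):
        raise ValueError("S(t) underflowed to 0; model degenerate at this t")
    return 1.0 - survival_at(model, covariates, t + 1.0) / s_t


def apply_hazard_ratio(p, hr) -> np.ndarray:
    """Adjust an annual probability by a hazard ratio.

    Assumes a constant hazard within the 1-year cycle, so the probability is
    converted to a rate, scaled, and converted back:
    ``1 - (1 - p)**hr``.  ``hr = 1`` is the identity; composition across
    multiplied hazard ratios is exact.
    """
    p = np.asarray(p, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hazard ratio must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** hr


@dataclass(frozen=True)
class MortalityAdjustment:
    """Hazard ratios on all-cause mortality in the diseased states.

    By default the complications HR applies relative to the general
    population (it replaces, not multiplies, the T2D HR); set
    ``complication_hr_on_top`` to stack it on the sex-specific T2D HR.
    """

    hr_t2d_female: float = 2.47
    hr_t2d_male: float = 1.93
    hr_complications: float = 2.36
    complication_hr_on_top: bool = False

    def __post_init__(self) -> None:
        for v in (self.hr_t2d_female, self.hr_t2d_male, self.hr_complications):
            if not v > 0:
                raise ValueError("mortality hazard ratios must be positive")

    def hr_t2d(self, sex) -> np.ndarray:
        """Sex-specific T2D mortality HR; sex coded 1 = male, 0 = female."""
        male = np.asarray(sex) == 1
        return np.where(male, self.hr_t2d_male, self.hr_t2d_female)

    def hr_for_complications(self, sex) -> np.ndarray:
        if self.complication_hr_on_top:
            return self.hr_t2d(sex) * self.hr_complications
        return np.broadcast_to(
            np.asarray(self.hr_complications, dtype=float), np.shape(sex) or ()
        )


class LifeTable:
    """Annual all-cause death probabilities ``q(age, sex)`` for ages 30-100.

    Stored as dense arrays per sex for O(1) vectorized lookup.
    """

    AGE_MIN, AGE_MAX = 30, 100

    def __init__(self, qx_female: Sequence[float], qx_male: Sequence[float]):
        n = self.AGE_MAX - self.AGE_MIN + 1
        self.qx = np.empty((2, n))  # row 0: female, row 1: male
        for row, qx in ((0, qx_female), (1, qx_male)):
            arr = np.asarray(qx, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"expected {n} annual probabilities, got {arr.shape}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("death probabilities must lie in [0, 1]")
            self.qx[row] = arr

    def q(self, age, sex) -> np.ndarray:
        """Annual death probability; sex coded 1 = male, 0 = female."""
        age = np.asarray(age)
        if np.any((age < self.AGE_MIN) | (age > self.AGE_MAX)):
            raise ValueError(
                f"age outside life table range [{self.AGE_MIN}, {self.AGE_MAX}]"
            )
        idx = np.asarray(age, dtype=int) - self.AGE_MIN
        return self.qx[np.asarray(sex, dtype=int), idx]

    def to_csv(self, path) -> None:
        ages = np.arange(self.AGE_MIN, self.AGE_MAX + 1)
        frames = []
        for sex, label in ((0, "female"), (1, "male")):
            frames.append(pd.DataFrame({"age": ages, "sex": label, "qx": self.qx[sex]}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        ages = np.arange(cls.AGE_MIN, cls.AGE_MAX + 1)
        out = {}
        for label in ("female", "male"):
            sub = df[df["sex"] == label].set_index("age")["qx"]
            out[label] = sub.reindex(ages).to_numpy()
            if np.any(np.isnan(out[label])):
                raise ValueError(f"life table incomplete for sex={label}")
        return cls(out["female"], out["male"])


def make_synthetic_life_table(
    makeham: float = 3e-4,
    gompertz_a_female: float = 1.2e-5,
    gompertz_a_male: float = 1.8e-5,
    gompertz_b: float = 0.10,
) -> LifeTable:
    """Synthetic all-cause life table from a Gompertz-Makeham hazard.

    Stands in for national life tables, which are not redistributable here.
    The hazard ``mu(age) = c + a * exp(b * age)`` with the defaults above
    yields remaining life expectancies at age 60 of roughly 22 (men) to 25
    (women) years, in the range of a contemporary high-income population.
    Annual probabilities are ``q = 1 - exp(-integral of mu over the year)``.
    """
    ages = np.arange(LifeTable.AGE_MIN, LifeTable.AGE_MAX + 1, dtype=float)

    def qx(a: float) -> np.ndarray:
        # exact integral of the Gompertz-Makeham hazard over [age, age+1]
        cum = makeham + (a / gompertz_b) * np.exp(gompertz_b * ages) * (
            np.exp(gompertz_b) - 1.0
        )
        return 1.0 - np.exp(-cum)

    return LifeTable(qx_female=qx(gompertz_a_female), qx_male=qx(gompertz_a_male))


def mortality_prob(
    life_table: LifeTable,
    age,
    sex,
    state,
    adjustment: MortalityAdjustment | None = None,
) -> np.ndarray:
    """Annual death probability in a health state.

    ``state`` is one of ``"healthy"``, ``"t2d"``, ``"t2d_complications"``
    (or the corresponding :class:`~t2dsim.microsim_engine.HealthState`).
    Healthy individuals face the raw life-table probability; the diseased
    states are adjusted by the corresponding hazard ratio under the
    constant-within-cycle hazard convention.
    """
    adjustment = adjustment or MortalityAdjustment()
    key = getattr(state, "name", state)
    key = str(key).lower()
    q = life_table.q(age, sex)
    if key == "healthy":
        return q
    if key == "t2d":
        return apply_hazard_ratio(q, adjustment.hr_t2d(sex))
    if key == "t2d_complications":
        return apply_hazard_ratio(q, adjustment.hr_for_complications(sex))
    if key == "dead":
        return np.ones_like(q)
    raise ValueError(f"unknown health state {key!r}")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class AFTFit:
    """Result of a right-censored parametric survival regression."""

    family: str
    model: WeibullAFTModel | None
    log_likelihood: float
    n_params: int
    n_obs: int
    converged: bool
    params: pd.Series = field(default_factory=pd.Series)
    standard_errors: pd.Series = field(default_factory=pd.Series)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.log_likelihood


def _as_frame(times, events, covariates) -> pd.DataFrame:
    df = pd.DataFrame(covariates).copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    return df


def _fit_lifelines(df: pd.DataFrame, family: str) -> AFTFit:
    from lifelines import (
        LogLogisticAFTFitter,
        LogNormalAFTFitter,
        WeibullAFTFitter,
    )

    fitters = {
        "weibull": WeibullAFTFitter,
        "lognormal": LogNormalAFTFitter,
        "loglogistic": LogLogisticAFTFitter,
    }
    fitter = fitters[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(df, duration_col="_time", event_col="_event")
    primary = fitter._primary_parameter_name  # lambda_ / mu_ / alpha_
    coef = fitter.params_[primary]
    intercept = float(coef["Intercept"])
    betas = {k: float(v) for k, v in coef.items() if k != "Intercept"}
    ancillary = fitter.params_.drop(primary)
    # rho_/sigma_/beta_ Intercept; lifelines models log of the ancillary
    anc_val = float(np.exp(ancillary.iloc[0]))
    if family == "weibull":
        scale = 1.0 / anc_val  # lifelines rho_ is the Weibull shape
        model = WeibullAFTModel(intercept=intercept, coefficients=betas, scale=scale)
    else:
        model = None  # only the Weibull family maps onto WeibullAFTModel
    return AFTFit(
        family=family,
        model=model,
        log_likelihood=float(fitter.log_likelihood_),
        n_params=len(fitter.params_),
        n_obs=len(df),
        converged=True,
        params=fitter.params_.copy(),
        standard_errors=fitter.standard_errors_.copy(),
    )


def _fit_exponential(df: pd.DataFrame) -> AFTFit:
    """Exponential AFT via Poisson GLM with a log-time offset.

    For a constant hazard ``h = exp(-(intercept + x.beta))`` the
    right-censored exponential log-likelihood coincides (up to a constant in
    the parameters) with a Poisson likelihood for the event indicator with
    offset ``log(t)``; the GLM solution is the exact MLE.
    """
    import statsmodels.api as sm

    covs = df.drop(columns=["_time", "_event"])
    X = sm.add_constant(covs, has_constant="add")
    glm = sm.GLM(
        df["_event"],
        X,
        family=sm.families.Poisson(),
        offset=np.log(df["_time"].to_numpy()),
    )
    res = glm.fit()
    # Poisson coefs model log-hazard; AFT log-lambda is its negative
    intercept = -float(res.params["const"])
    betas = {k: -float(v) for k, v in res.params.items() if k != "const"}
    model = WeibullAFTModel(intercept=intercept, coefficients=betas, scale=1.0)
    # exact exponential log-likelihood: sum(d*log h - h*t)
    h = np.exp(-model.linear_predictor(covs))
    d = df["_event"].to_numpy()
    ll = float(np.sum(d * np.log(h) - h * df["_time"].to_numpy()))
    params = pd.Series(
        {("lambda_", "Intercept"): intercept}
        | {("lambda_", k): v for k, v in betas.items()}
    )
    ses = pd.Series(
        {("lambda_", "Intercept"): float(res.bse["const"])}
        | {("lambda_", k): float(res.bse[k]) for k in betas}
    )
    return AFTFit(
        family="exponential",
        model=model,
        log_likelihood=ll,
        n_params=len(res.params),
        n_obs=len(df),
        converged=bool(res.converged),
        params=params,
        standard_errors=ses,
    )


def fit_aft(times, events, covariates, family: str = "weibull") -> AFTFit:
    """Fit a right-censored parametric AFT survival regression.

    Parameters
    ----------
    times, events
        Follow-up times and event indicators (1 = event, 0 = censored).
    covariates
        Mapping or DataFrame of covariate columns.
    family
        One of ``exponential``, ``weibull``, ``lognormal``, ``loglogistic``.

    Returns
    -------
    AFTFit with the maximized log-likelihood, AIC/BIC, and — for the
    exponential and weibull families — the fitted :class:`WeibullAFTModel`.
    """
    if family not in AFT_FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {AFT_FAMILIES}")
    events_arr = np.asarray(events, dtype=int)
    if events_arr.sum() == 0:
        raise ValueError("no events observed; cannot fit a survival model")
    df = _as_frame(times, events, covariates)
    if np.any(df["_time"] <= 0):
        raise ValueError("all times must be positive")
    if family == "exponential":
        return _fit_exponential(df)
    return _fit_lifelines(df, family)


def compare_families(
    times, events, covariates, families: Iterable[str] = AFT_FAMILIES
) -> tuple[pd.DataFrame, str]:
    """Fit several parametric families and select by information criteria.

    Returns a table with one row per family (log-likelihood, number of
    parameters, AIC, BIC, convergence, error message if the fit failed) and
    the name of the selected family: lowest AIC, ties broken by lowest BIC.
    """
    families = list(families)
    if len(families) < 2:
        raise ValueError("need at least two families to compare")
    rows = []
    for fam in families:
        try:
            fit = fit_aft(times, events, covariates, family=fam)
            rows.append(
                {
                    "family": fam,
                    "log_likelihood": fit.log_likelihood,
                    "n_params": fit.n_params,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "converged": fit.converged,
                    "error": "",
                }
            )
        except Exception as exc:  # propagate per-family failure in the table
            rows.append(
                {
                    "family": fam,
                    "log_likelihood": np.nan,
                    "n_params": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows).set_index("family")
    ok = table.dropna(subset=["aic"])
    if ok.empty:
        raise RuntimeError("every family failed to fit")
    best = ok.sort_values(["aic", "bic"]).index[0]
    return table, best
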