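"""Parameter uncertainty and decision analytics.

Distribution parameterization from printed means, standard errors and
confidence intervals (method of moments for beta, gamma and lognormal
families), probabilistic sensitivity analysis (PSA) sampling, incremental
cost-effectiveness (ICER/dominance), net monetary benefit, the
cost-effectiveness acceptability curve (CEAC), the expected value of
perfect information (EVPI), the cost-neutral test price, and the
deterministic scenario runner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import economics
from .microsim_engine import (
    InterventionPolicy,
    ModelSet,
    ParameterSet,
    draw_streams,
    run_pair,
)
from .survival_models import MortalityAdjustment

logger = logging.getLogger(__name__)

__all__ = [
    "ParamDistribution",
    "PSAResult",
    "IncrementalResult",
    "se_from_ci",
    "pm25_bounds",
    "beta_mom",
    "gamma_mom",
    "lognormal_mom",
    "round_half_up",
    "sample_parameters",
    "build_parameter_set",
    "default_distributions",
    "incremental_analysis",
    "nmb",
    "ceac",
    "evpi",
    "cost_neutral_price",
    "run_base_case",
    "run_psa",
    "run_scenarios",
    "SCENARIOS",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with halves away from zero, matching printed-table rounding."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def se_from_ci(lower: float, upper: float) -> float:
    """Standard error from a 95% CI: ``(upper - lower) / (2 * 1.96)``."""
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    return (upper - lower) / (2.0 * 1.96)


class Pm25Bounds(NamedTuple):
    lower: float
    upper: float
    se: float


def pm25_bounds(mean: float) -> Pm25Bounds:
    """±25% variation bounds for parameters without a published CI,
    with the standard error the CI rule implies for them."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    lower, upper = 0.75 * mean, 1.25 * mean
    return Pm25Bounds(lower, upper, se_from_ci(lower, upper))


def beta_mom(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta parameters from a mean and standard error:
    ``nu = m(1-m)/se^2 - 1``, ``alpha = m*nu``, ``beta = (1-m)*nu``."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie in (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    if se * se >= mean * (1.0 - mean):
        raise ValueError("variance too large for a beta distribution")
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_mom(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, rate): ``shape = (m/se)^2``,
    ``rate = m/se^2``; the round trip is exact."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    return (mean / se) ** 2, mean / (se * se)


def lognormal_mom(mean: float, se: float) -> tuple[float, float]:
    """Natural-scale moment-matched lognormal (mu, sigma):
    ``sigma^2 = ln(1 + (se/m)^2)``, ``mu = ln(m) - sigma^2/2``."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    sigma2 = math.log1p((se / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class ParamDistribution:
    """A PSA sampling recipe for one model parameter.

    ``family`` is one of ``lognormal``, ``gamma``, ``beta``, ``fixed``.
    Beta rows may carry published ``alpha``/``beta`` shape terms, which take
    precedence over the method-of-moments fit from mean/SE.
    """

    name: str
    family: str
    mean: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "beta", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "fixed" and self.se is None and self.alpha is None:
            raise ValueError(f"{self.name}: non-fixed distribution needs an SE")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.name}: se must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        if self.family == "lognormal":
            mu, sigma = lognormal_mom(self.mean, self.se)
            return float(rng.lognormal(mu, sigma))
        if self.family == "gamma":
            shape, rate = gamma_mom(self.mean, self.se)
            return float(rng.gamma(shape, 1.0 / rate))
        if self.alpha is not None and self.beta is not None:
            return float(rng.beta(self.alpha, self.beta))
        a, b = beta_mom(self.mean, self.se)
        return float(rng.beta(a, b))


def sample_parameters(
    distributions: Mapping[str, ParamDistribution], rng: np.random.Generator
) -> dict[str, float]:
    """One independent draw from every distribution (fixed pass through)."""
    return {name: dist.sample(rng) for name, dist in distributions.items()}


def default_distributions(parameter_file=None) -> dict[str, ParamDistribution]:
    """Load the shipped (or a user) parameter file into distributions."""
    import yaml
    from importlib import resources

    if parameter_file is None:
        text = (
            resources.files("t2dsim").joinpath("data/parameters.yaml").read_text()
        )
        raw = yaml.safe_load(text)
    else:
        with open(parameter_file) as fh:
            raw = yaml.safe_load(fh)
    out = {}
    for name, row in raw["parameters"].items():
        out[name] = ParamDistribution(
            name=name,
            family=row["family"],
            mean=float(row["mean"]),
            se=float(row["se"]) if row.get("se") is not None else None,
            ci=tuple(row["ci"]) if row.get("ci") else None,
            alpha=float(row["alpha"]) if row.get("alpha") is not None else None,
            beta=float(row["beta"]) if row.get("beta") is not None else None,
        )
    return out


def build_parameter_set(
    values: Mapping[str, float],
    base_policy: InterventionPolicy | None = None,
    prs_test_price: float | None = None,
) -> tuple[ParameterSet, InterventionPolicy]:
    """Assemble an engine ParameterSet + InterventionPolicy from sampled
    (or base-case mean) parameter values keyed by the parameter-file names."""
    base_policy = base_policy or InterventionPolicy()
    v = dict(values)
    costs = economics.CostParameters(
        productivity_t2d=v["cost_productivity_t2d"],
        complications_extra=v["cost_complications"],
        t2d_secondary_care=v["cost_t2d_secondary"],
        medical_therapy_annual=v["cost_medical_therapy"],
        lifestyle_intervention=v["cost_lifestyle"],
        prs_test=prs_test_price if prs_test_price is not None else v["cost_prs_test"],
        t2d_primary_care_male=v["cost_primary_male"],
        t2d_primary_care_female=v["cost_primary_female"],
        t2d_medication=v["cost_t2d_medication"],
    )
    baseline = {
        ("female", "30-44"): v["utility_female_30_44"],
        ("female", "45-54"): v["utility_female_45_54"],
        ("female", "55-64"): v["utility_female_55_64"],
        ("female", "65+"): v["utility_female_65plus"],
        ("male", "30-44"): v["utility_male_30_44"],
        ("male", "45-54"): v["utility_male_45_54"],
        ("male", "55-64"): v["utility_male_55_64"],
        ("male", "65+"): v["utility_male_65plus"],
    }
    utilities = economics.UtilityParameters(
        baseline=baseline,
        disutility_t2d=v["disutility_t2d"],
        disutility_complications=v["disutility_complications"],
    )
    mortality = MortalityAdjustment(
        hr_t2d_female=v["hr_mort_t2d_female"],
        hr_t2d_male=v["hr_mort_t2d_male"],
        hr_complications=v["hr_mort_complications"],
    )
    policy = replace(
        base_policy,
        hr_lifestyle=min(v["hr_lifestyle"], 1.0),
        hr_combined=min(v["hr_combined"], 1.0),
    )
    return ParameterSet(mortality=mortality, costs=costs, utilities=utilities), policy


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost-effectiveness of the PRS arm vs. usual care."""

    delta_cost: float
    delta_qaly: float
    icer: float  # NaN when a label replaces the ratio
    label: str  # "dominant", "dominated", "icer", "undefined", "equivalent"

    def display(self) -> str:
        if self.label == "icer":
            return f"{self.icer:.0f}"
        return self.label


def incremental_analysis(
    mean_cost_usual: float,
    mean_qaly_usual: float,
    mean_cost_prs: float,
    mean_qaly_prs: float,
) -> IncrementalResult:
    """Dominance check first; an ICER only where neither arm dominates."""
    dc = mean_cost_prs - mean_cost_usual
    de = mean_qaly_prs - mean_qaly_usual
    if dc < 0 and de > 0:
        return IncrementalResult(dc, de, float("nan"), "dominant")
    if dc > 0 and de < 0:
        return IncrementalResult(dc, de, float("nan"), "dominated")
    if de == 0:
        label = "equivalent" if dc == 0 else "undefined"
        return IncrementalResult(dc, de, float("nan"), label)
    return IncrementalResult(dc, de, dc / de, "icer")


def nmb(cost, qaly, wtp):
    """Net monetary benefit ``wtp * qaly - cost``."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness to pay must be non-negative")
    return np.asarray(wtp) * np.asarray(qaly) - np.asarray(cost)


@dataclass
class PSAResult:
    """Paired per-draw expected outcomes of the two strategies."""

    draws: pd.DataFrame  # cost_usual, qaly_usual, cost_prs, qaly_prs per draw
    wtp_grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.wtp_grid, dtype=float)
        if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("WTP grid must be non-negative and increasing")
        self.wtp_grid = grid

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def delta_nmb(self, wtp: float) -> np.ndarray:
        d = self.draws
        return np.asarray(
            nmb(d["cost_prs"], d["qaly_prs"], wtp)
            - nmb(d["cost_usual"], d["qaly_usual"], wtp)
        )


def ceac(psa: PSAResult) -> pd.DataFrame:
    """Probability the PRS strategy has the higher net monetary benefit at
    each WTP grid point; exact ties count one half."""
    if psa.n_draws < 1:
        raise ValueError("need at least one PSA draw")
    probs = []
    for wtp in psa.wtp_grid:
        d = psa.delta_nmb(float(wtp))
        probs.append(float(np.mean((d > 0) + 0.5 * (d == 0))))
    return pd.DataFrame({"wtp": psa.wtp_grid, "p_prs_cost_effective": probs})


def evpi(psa: PSAResult, wtp: float) -> float:
    """Expected value of perfect information at one WTP threshold:
    mean over draws of the best-strategy NMB minus the best of the mean
    NMBs.  Non-negative; zero when one strategy wins every draw."""
    if psa.n_draws < 1:
        raise ValueError("need at least one PSA draw")
    d = psa.draws
    nmb_u = np.asarray(nmb(d["cost_usual"], d["qaly_usual"], wtp))
    nmb_p = np.asarray(nmb(d["cost_prs"], d["qaly_prs"], wtp))
    perfect = float(np.mean(np.maximum(nmb_u, nmb_p)))
    current = float(max(nmb_u.mean(), nmb_p.mean()))
    return perfect - current


def evpi_curve(psa: PSAResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": psa.wtp_grid, "evpi": [evpi(psa, float(w)) for w in psa.wtp_grid]}
    )


def cost_neutral_price(delta_cost: float, base_test_price: float) -> float:
    """PRS test price at which the incremental cost is zero.

    Every PRS-arm member is tested exactly once at an undiscounted year-1
    charge, so the incremental cost moves one-for-one with the price:
    the neutral point is ``base_test_price - delta_cost``.  A negative
    result is floored at zero (the test cannot be paid to be given).
    """
    if base_test_price < 0:
        raise ValueError("base_test_price must be non-negative")
    price = base_test_price - delta_cost
    if price < 0:
        logger.warning("cost-neutral price %.2f below zero; reporting 0", price)
        return 0.0
    return price


# ---------------------------------------------------------------------------
# pipeline runners


def _make_target_cohort(config, models: ModelSet, n_target: int, seed: int) -> pd.DataFrame:
    """Generate synthetic adults and keep the first ``n_target`` members of
    the 10-20% screening band, topping up in chunks as needed."""
    from .synthetic_population import (
        CohortSpec,
        attach_risks,
        generate_cohort,
        select_target_population,
    )

    spec_kwargs = dict(config.cohort_overrides or {})
    chunks: list[pd.DataFrame] = []
    total = 0
    chunk_n = max(2000, int(n_target * 8))
    sub_seed = seed
    while total < n_target:
        spec = CohortSpec(n=chunk_n, seed=sub_seed, **spec_kwargs)
        cohort = attach_risks(
            generate_cohort(spec), models.t2d_screen_no_prs, models.t2d_screen_with_prs
        )
        selected, _ = select_target_population(cohort)
        chunks.append(selected)
        total += len(selected)
        sub_seed += 1
    out = pd.concat(chunks, ignore_index=True).head(n_target).copy()
    out["id"] = np.arange(len(out))
    return out


def run_base_case(
    config,
    models: ModelSet | None = None,
    n_per_arm: int | None = None,
    discount_rate: float | None = None,
    horizon_years: int | None = "config",
    include_productivity: bool | None = None,
    cohort: pd.DataFrame | None = None,
    streams=None,
) -> dict:
    """Deterministic (mean-parameter) run of both arms.

    Returns the two arm summaries, the incremental analysis, the
    reclassification rate, and the cost-neutral PRS test price.  Keyword
    overrides support the scenario runner; pass ``cohort``/``streams`` to
    reuse them across scenarios.
    """
    models = models or ModelSet.defaults()
    n_per_arm = n_per_arm or config.n_per_arm
    rate = config.discount_rate if discount_rate is None else discount_rate
    horizon = config.horizon if horizon_years == "config" else horizon_years
    prod = config.include_productivity if include_productivity is None else include_productivity

    dists = default_distributions(config.parameter_file)
    means = {name: d.mean for name, d in dists.items()}
    params, policy = build_parameter_set(
        means, config.base_policy(), prs_test_price=config.prs_test_price
    )
    if cohort is None:
        cohort = _make_target_cohort(config, models, n_per_arm, seed=config.seed)
    if streams is None:
        t_max = int((100 - cohort["age"].to_numpy(dtype=int)).max())
        streams = draw_streams(len(cohort), t_max, config.seed + 1)
    usual, prs = run_pair(
        cohort,
        models,
        params,
        policy,
        streams,
        discount_rate=rate,
        include_productivity=prod,
        horizon_years=horizon,
    )
    inc = incremental_analysis(
        usual.mean_cost, usual.mean_qaly, prs.mean_cost, prs.mean_qaly
    )
    return {
        "usual": usual,
        "prs": prs,
        "incremental": inc,
        "reclassification_rate": prs.reclassified_fraction,
        "cost_neutral_price": cost_neutral_price(inc.delta_cost, config.prs_test_price),
        "cohort": cohort,
        "streams": streams,
    }


def run_psa(config, models: ModelSet | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw samples a full parameter set, generates a fresh target cohort
    of ``n_per_arm`` individuals, and runs both arms under common random
    numbers; first-order individual noise is averaged within the draw
    before any decision statistic is computed.
    """
    models = models or ModelSet.defaults()
    dists = default_distributions(config.parameter_file)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_draws)
    rows = []
    for i, child in enumerate(children):
        param_ss, cohort_ss, stream_ss = child.spawn(3)
        rng = np.random.default_rng(param_ss)
        values = sample_parameters(dists, rng)
        params, policy = build_parameter_set(
            values, config.base_policy(), prs_test_price=config.prs_test_price
        )
        cohort_seed = int(cohort_ss.generate_state(1)[0] >> 1)
        cohort = _make_target_cohort(config, models, config.n_per_arm, seed=cohort_seed)
        t_max = int((100 - cohort["age"].to_numpy(dtype=int)).max())
        if config.horizon is not None:
            t_max = min(t_max, config.horizon)
        streams = draw_streams(len(cohort), t_max, stream_ss)
        usual, prs = run_pair(
            cohort,
            models,
            params,
            policy,
            streams,
            discount_rate=config.discount_rate,
            include_productivity=config.include_productivity,
            horizon_years=config.horizon,
        )
        rows.append(
            {
                "draw": i,
                "cost_usual": usual.mean_cost,
                "qaly_usual": usual.mean_qaly,
                "cost_prs": prs.mean_cost,
                "qaly_prs": prs.mean_qaly,
                "reclassified_fraction": prs.reclassified_fraction,
            }
        )
        if (i + 1) % 10 == 0:
            logger.info("PSA draw %d/%d complete", i + 1, config.n_draws)
    return PSAResult(draws=pd.DataFrame(rows), wtp_grid=config.wtp_grid())


SCENARIOS = (
    "base_case",
    "discount_0pct",
    "discount_5pct",
    "no_productivity_costs",
    "horizon_10y",
    "horizon_20y",
)


def run_scenarios(config, models: ModelSet | None = None) -> pd.DataFrame:
    """Deterministic scenario table: base case plus discount-rate, horizon
    and productivity-cost variations, one row each, sharing the base-case
    cohort and random streams so rows differ only by the scenario itself."""
    models = models or ModelSet.defaults()
    base = run_base_case(config, models)
    cohort, streams = base["cohort"], base["streams"]
    overrides = {
        "base_case": {},
        "discount_0pct": {"discount_rate": 0.0},
        "discount_5pct": {"discount_rate": 0.05},
        "no_productivity_costs": {"include_productivity": False},
        "horizon_10y": {"horizon_years": 10},
        "horizon_20y": {"horizon_years": 20},
    }
    rows = []
    for name in SCENARIOS:
        try:
            if name == "base_case":
                result = base
            else:
                result = run_base_case(
                    config, models, cohort=cohort, streams=streams, **overrides[name]
                )
            inc = result["incremental"]
            rows.append(
                {
                    "scenario": name,
                    "cost_usual": result["usual"].mean_cost,
                    "qaly_usual": result["usual"].mean_qaly,
                    "cost_prs": result["prs"].mean_cost,
                    "qaly_prs": result["prs"].mean_qaly,
                    "delta_cost": inc.delta_cost,
                    "delta_qaly": inc.delta_qaly,
                    "icer": inc.display(),
                    "cost_neutral_price": result["cost_neutral_price"],
                    "error": "",
                }
            )
        except Exception as exc:  # keep other scenario rows alive
            logger.exception("scenario %s failed", name)
            rows.append({"scenario": name, "error": str(exc)})
    return pd.DataFrame(rows)
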