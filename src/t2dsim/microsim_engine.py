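"""Four-state annual-cycle individual-level simulation.

States and transitions
----------------------
``HEALTHY -> T2D -> T2D_COMPLICATIONS``, any state ``-> DEAD`` (absorbing),
plus self-loops.  One cycle is one year; an individual's simulation ends at
death or on reaching age 100, whichever comes first.

Within a cycle mortality is drawn first; survivors then face at most one
disease-progression event (T2D onset from HEALTHY, or a first complication
from T2D, with the complication clock running from the year of onset).
Costs and utilities accrue by the state occupied after the cycle's
transitions; a cycle in which the individual dies accrues nothing beyond
the baseline screening charges of cycle 1.

Both strategy arms share a single matrix of uniform random draws per cohort
(common random numbers), so that strategies differing only in labels or
prices produce exactly identical trajectories.

The production path, :func:`run_arm`, is vectorized across individuals; the
per-person :func:`simulate_individual` is the readable reference
implementation and the two agree on shared draws up to summation-order
round-off (< 1e-9 on per-person totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

from .survival_models import (
    LifeTable,
    MortalityAdjustment,
    WeibullAFTModel,
    annual_event_prob,
    apply_hazard_ratio,
)

__all__ = [
    "HealthState",
    "Strategy",
    "InterventionStatus",
    "InterventionPolicy",
    "ParameterSet",
    "ModelSet",
    "Trajectory",
    "ArmResult",
    "UniformStreams",
    "draw_streams",
    "classify_risk",
    "assign_intervention",
    "assign_interventions",
    "effective_t2d_prob",
    "step",
    "simulate_individual",
    "run_arm",
    "run_pair",
    "reclassification_rate",
]


class HealthState(IntEnum):
    HEALTHY = 0
    T2D = 1
    T2D_COMPLICATIONS = 2
    DEAD = 3


class Strategy(str, Enum):
    """Screening strategies: usual risk-factor screening vs. targeted PRS."""

    USUAL = "usual"
    PRS = "prs"


class InterventionStatus(IntEnum):
    NONE = 0
    LIFESTYLE = 1
    LIFESTYLE_MEDICAL = 2


@dataclass(frozen=True)
class InterventionPolicy:
    """Who is intervened on and what the intervention does.

    A 10-year T2D risk at or above ``risk_threshold`` triggers a lifestyle
    intervention; a fraction ``medical_uptake`` of those also receive
    medical therapy.  The incidence hazard ratios apply while the effect
    lasts (``effect_duration`` years from screening).  Medical-therapy cost
    is charged annually for ``medical_therapy_years``.
    """

    risk_threshold: float = 0.20
    hr_lifestyle: float = 0.74
    hr_combined: float = 0.51
    effect_duration: float = 15.0
    medical_uptake: float = 0.30
    adherence: float = 1.0  # full adherence assumed
    medical_therapy_years: int = 1

    def __post_init__(self) -> None:
        for name in ("hr_lifestyle", "hr_combined"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.effect_duration < 0:
            raise ValueError("effect_duration must be non-negative")
        if not 0.0 <= self.medical_uptake <= 1.0:
            raise ValueError("medical_uptake must lie in [0, 1]")


@dataclass(frozen=True)
class ParameterSet:
    """One complete draw of model parameters: the unit of the PSA.

    Bundles the mortality hazard ratios with the cost and utility inputs;
    intervention-effect hazard ratios travel in :class:`InterventionPolicy`.
    """

    mortality: "MortalityAdjustment"
    costs: "economics.CostParameters"
    utilities: "economics.UtilityParameters"

    @classmethod
    def base_case(cls) -> "ParameterSet":
        from . import economics

        return cls(
            mortality=MortalityAdjustment(),
            costs=economics.CostParameters(),
            utilities=economics.UtilityParameters(),
        )


@dataclass(frozen=True)
class ModelSet:
    """The fitted/stipulated survival models and life table the engine uses.

    ``t2d_truth`` drives actual disease onset in both arms (it carries the
    PRS effect); the two screening models only produce the predicted risks
    used for intervention assignment.
    """

    t2d_truth: WeibullAFTModel
    t2d_screen_no_prs: WeibullAFTModel
    t2d_screen_with_prs: WeibullAFTModel
    complications: WeibullAFTModel
    life_table: LifeTable

    @classmethod
    def defaults(cls) -> "ModelSet":
        from . import defaults

        with_prs = defaults.default_t2d_model_with_prs()
        return cls(
            t2d_truth=with_prs,
            t2d_screen_no_prs=defaults.default_t2d_model_no_prs(),
            t2d_screen_with_prs=with_prs,
            complications=defaults.default_complication_model(),
            life_table=defaults.default_life_table(),
        )


RISK_CATEGORIES = ("very_low", "low", "moderate", "high", "very_high")
DEFAULT_RISK_EDGES = (0.025, 0.05, 0.10, 0.20)


def classify_risk(risk10, edges=DEFAULT_RISK_EDGES):
    """Five-category 10-year risk classification.

    The consequential edges are 0.10 (entry to the high band) and 0.20
    (very-high, triggering intervention); the intervals are half-open, so a
    risk of exactly 0.20 is very-high.
    """
    risk10 = np.asarray(risk10, dtype=float)
    if np.any((risk10 < 0) | (risk10 > 1)):
        raise ValueError("risk10 must lie in [0, 1]")
    idx = np.searchsorted(np.asarray(edges), risk10, side="right")
    if risk10.shape:
        return np.asarray(RISK_CATEGORIES, dtype=object)[idx]
    return RISK_CATEGORIES[int(idx)]


def assign_interventions(
    cohort: pd.DataFrame,
    strategy: Strategy,
    policy: InterventionPolicy,
    u_uptake: np.ndarray,
) -> np.ndarray:
    """Vectorized intervention assignment for a whole cohort.

    The usual arm screens on ``risk10_no_prs``, the PRS arm on
    ``risk10_with_prs``; crossing the threshold assigns the lifestyle
    intervention, with medical therapy added where the uptake draw falls
    below ``medical_uptake``.
    """
    col = "risk10_with_prs" if strategy == Strategy.PRS else "risk10_no_prs"
    if col not in cohort.columns:
        raise ValueError(f"cohort lacks required risk column {col!r}")
    risks = cohort[col].to_numpy(dtype=float)
    if np.any(np.isnan(risks)):
        raise ValueError(f"risk column {col!r} contains missing values")
    status = np.where(risks >= policy.risk_threshold, InterventionStatus.LIFESTYLE, 0)
    medical = (status > 0) & (np.asarray(u_uptake) < policy.medical_uptake)
    status = np.where(medical, InterventionStatus.LIFESTYLE_MEDICAL, status)
    return status.astype(int)


def assign_intervention(individual, strategy, policy: InterventionPolicy, rng) -> InterventionStatus:
    """Single-person intervention assignment (see :func:`assign_interventions`)."""
    frame = pd.DataFrame([dict(individual)])
    u = np.asarray([rng.random() if hasattr(rng, "random") else float(rng)])
    return InterventionStatus(int(assign_interventions(frame, strategy, policy, u)[0]))


def effective_t2d_prob(base_p, status, years_since_start, policy: InterventionPolicy):
    """Annual T2D onset probability under the active intervention.

    While the effect lasts (``years_since_start < effect_duration``) the
    lifestyle hazard ratio — or the combined lifestyle+medical one — is
    applied under the constant-within-cycle hazard convention; afterwards
    the baseline probability returns unchanged.
    """
    base_p = np.asarray(base_p, dtype=float)
    status = np.asarray(status, dtype=int)
    active = (status > 0) & (np.asarray(years_since_start) < policy.effect_duration)
    hr = np.where(status == InterventionStatus.LIFESTYLE_MEDICAL, policy.hr_combined, policy.hr_lifestyle)
    adjusted = apply_hazard_ratio(base_p, hr)
    out = np.where(active, adjusted, base_p)
    return out if out.shape else float(out)


def step(state, q_death, p_t2d, p_comp, u_death, u_prog):
    """One annual-cycle transition for one individual.

    Mortality is drawn first; a survivor then faces at most one progression
    event: T2D onset from HEALTHY, or a first complication from T2D.
    T2D_COMPLICATIONS has no further progression.  DEAD is absorbing and
    may not be stepped.
    """
    state = HealthState(state)
    if state == HealthState.DEAD:
        raise ValueError("cannot step an individual already in DEAD")
    if u_death < q_death:
        return HealthState.DEAD
    if state == HealthState.HEALTHY and u_prog < p_t2d:
        return HealthState.T2D
    if state == HealthState.T2D and u_prog < p_comp:
        return HealthState.T2D_COMPLICATIONS
    return state


@dataclass
class UniformStreams:
    """Pre-drawn uniforms shared across arms (common random numbers)."""

    death: np.ndarray  # (n, t_max)
    prog: np.ndarray  # (n, t_max)
    uptake: np.ndarray  # (n,)

    @property
    def n(self) -> int:
        return self.death.shape[0]

    @property
    def t_max(self) -> int:
        return self.death.shape[1]


def draw_streams(n: int, t_max: int, seed) -> UniformStreams:
    rng = np.random.default_rng(seed)
    return UniformStreams(
        death=rng.random((n, t_max)),
        prog=rng.random((n, t_max)),
        uptake=rng.random(n),
    )


@dataclass
class Trajectory:
    """One simulated life course, one record per annual cycle."""

    ages: list = field(default_factory=list)
    states: list = field(default_factory=list)
    years_since_onset: list = field(default_factory=list)  # -1 before onset
    intervention_active: list = field(default_factory=list)
    costs: list = field(default_factory=list)  # undiscounted, per cycle
    utilities: list = field(default_factory=list)

    def append(self, age, state, ys_onset, active, cost, utility) -> None:
        self.ages.append(int(age))
        self.states.append(HealthState(state))
        self.years_since_onset.append(int(ys_onset))
        self.intervention_active.append(bool(active))
        self.costs.append(float(cost))
        self.utilities.append(float(utility))

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final_state(self) -> HealthState:
        return self.states[-1]


@dataclass
class ArmResult:
    """Aggregated per-person outcomes of one strategy arm."""

    strategy: Strategy
    n: int
    mean_cost: float
    mean_qaly: float
    mean_years_t2d_free: float
    mean_years_complication_free: float
    death_fraction: float
    reclassified_fraction: float
    per_individual: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "n": self.n,
            "mean_cost": self.mean_cost,
            "mean_qaly": self.mean_qaly,
            "mean_years_t2d_free": self.mean_years_t2d_free,
            "mean_years_complication_free": self.mean_years_complication_free,
            "death_fraction": self.death_fraction,
            "reclassified_fraction": self.reclassified_fraction,
        }


def reclassification_rate(cohort: pd.DataFrame, threshold: float = 0.20) -> float:
    """Fraction of the (high-band) target population whose PRS-informed
    10-year risk reaches the very-high threshold."""
    if len(cohort) == 0:
        return 0.0
    return float((cohort["risk10_with_prs"].to_numpy() >= threshold).mean())


def _baseline_charges(status: np.ndarray, is_prs_arm: bool, costs) -> np.ndarray:
    """One-off screening-time charges: PRS test (PRS arm, everyone),
    lifestyle course, and the first medical-therapy year."""
    charge = np.zeros(status.shape)
    if is_prs_arm:
        charge += costs.prs_test
    charge += np.where(status >= InterventionStatus.LIFESTYLE, costs.lifestyle_intervention, 0.0)
    charge += np.where(status == InterventionStatus.LIFESTYLE_MEDICAL, costs.medical_therapy_annual, 0.0)
    return charge


def simulate_individual(
    individual: Mapping,
    strategy: Strategy,
    models: ModelSet,
    params: ParameterSet,
    policy: InterventionPolicy,
    streams_row: tuple[np.ndarray, np.ndarray, float],
    discount_rate: float = 0.03,
    include_productivity: bool = True,
    horizon_years: int | None = None,
) -> Trajectory:
    """Reference per-person simulation; see the module docstring for the
    cycle semantics.  ``streams_row`` is ``(u_death, u_prog, u_uptake)``
    for this individual."""
    from . import economics

    u_death, u_prog, u_uptake = streams_row
    row = dict(individual)
    age0, sex = int(row["age"]), int(row["sex"])
    status = int(
        assign_intervention(row, strategy, policy, float(u_uptake))
    )
    covars = {k: row[k] for k in models.t2d_truth.coefficients}
    comp_covars = {k: row[k] for k in models.complications.coefficients}

    traj = Trajectory()
    state = HealthState.HEALTHY
    onset_year = -1
    t = 0
    t_stop = 100 - age0 if horizon_years is None else min(horizon_years, 100 - age0)
    while t < t_stop and state != HealthState.DEAD:
        age_t = age0 + t
        from .survival_models import mortality_prob

        q = float(mortality_prob(models.life_table, age_t, sex, state, params.mortality))
        p_t2d = p_comp = 0.0
        if state == HealthState.HEALTHY:
            base_p = float(annual_event_prob(models.t2d_truth, covars, t))
            p_t2d = float(effective_t2d_prob(base_p, status, t, policy))
        elif state == HealthState.T2D:
            p_comp = float(
                annual_event_prob(models.complications, comp_covars, t - onset_year)
            )
        new_state = step(state, q, p_t2d, p_comp, u_death[t], u_prog[t])
        if state == HealthState.HEALTHY and new_state == HealthState.T2D:
            onset_year = t
        cost = 0.0
        utility = 0.0
        if new_state != HealthState.DEAD:
            cost = float(
                economics.annual_cost(
                    new_state,
                    age_t,
                    sex,
                    params.costs,
                    include_productivity=include_productivity,
                    medical_this_year=(
                        1 <= t < policy.medical_therapy_years
                        and status == InterventionStatus.LIFESTYLE_MEDICAL
                    ),
                )
            )
            utility = float(economics.annual_utility(new_state, age_t, sex, params.utilities))
        if t == 0:
            cost += float(
                _baseline_charges(
                    np.asarray(status), strategy == Strategy.PRS, params.costs
                )
            )
        ys = (t - onset_year) if onset_year >= 0 else -1
        active = status > 0 and t < policy.effect_duration
        traj.append(age_t, new_state, ys, active, cost, utility)
        state = new_state
        t += 1
    return traj


def run_arm(
    cohort: pd.DataFrame,
    strategy: Strategy,
    models: ModelSet,
    params: ParameterSet,
    policy: InterventionPolicy,
    rng,
    discount_rate: float = 0.03,
    include_productivity: bool = True,
    horizon_years: int | None = None,
) -> ArmResult:
    """Simulate one strategy arm for a whole cohort (vectorized).

    ``rng`` may be an integer seed, a ``numpy.random.Generator``, or a
    pre-drawn :class:`UniformStreams`; pass the same streams to both arms
    for common random numbers.
    """
    from . import economics

    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    age0 = cohort["age"].to_numpy(dtype=int)
    sex = cohort["sex"].to_numpy(dtype=int)
    t_stop_i = (100 - age0).astype(int)
    if horizon_years is not None:
        t_stop_i = np.minimum(t_stop_i, horizon_years)
    t_max = int(t_stop_i.max())

    if isinstance(rng, UniformStreams):
        streams = rng
        if streams.n != n or streams.t_max < t_max:
            raise ValueError("uniform streams do not cover this cohort/horizon")
    else:
        seed = rng if not hasattr(rng, "random") else rng
        streams = draw_streams(n, t_max, seed)

    status = assign_interventions(cohort, strategy, policy, streams.uptake)
    truth_covars = {k: cohort[k].to_numpy(dtype=float) for k in models.t2d_truth.coefficients}
    comp_covars = {k: cohort[k].to_numpy(dtype=float) for k in models.complications.coefficients}

    state = np.zeros(n, dtype=int)  # HEALTHY
    onset_year = np.full(n, -1, dtype=int)
    total_cost = _baseline_charges(status, strategy == Strategy.PRS, params.costs)
    total_qaly = np.zeros(n)
    years_alive = np.zeros(n, dtype=int)
    years_t2d_free = np.zeros(n, dtype=int)
    years_comp_free = np.zeros(n, dtype=int)

    hr_t2d_mort = params.mortality.hr_t2d(sex)
    hr_comp_mort = params.mortality.hr_for_complications(sex)

    for t in range(t_max):
        active = (state != HealthState.DEAD) & (t < t_stop_i)
        if not active.any():
            break
        age_t = age0 + t
        age_q = np.where(active, age_t, LifeTable.AGE_MIN)
        q = models.life_table.q(age_q, sex)
        hr = np.where(
            state == HealthState.T2D,
            hr_t2d_mort,
            np.where(state == HealthState.T2D_COMPLICATIONS, hr_comp_mort, 1.0),
        )
        q_adj = np.where(state == HealthState.HEALTHY, q, apply_hazard_ratio(q, hr))
        died = active & (streams.death[:, t] < q_adj)

        healthy = active & ~died & (state == HealthState.HEALTHY)
        base_p = np.zeros(n)
        if healthy.any():
            base_p[healthy] = annual_event_prob(
                models.t2d_truth,
                {k: v[healthy] for k, v in truth_covars.items()},
                float(t),
            )
        p_eff = effective_t2d_prob(base_p, status, t, policy)
        onset = healthy & (streams.prog[:, t] < np.asarray(p_eff))

        t2d = active & ~died & (state == HealthState.T2D)
        p_comp = np.zeros(n)
        if t2d.any():
            p_comp[t2d] = annual_event_prob(
                models.complications,
                {k: v[t2d] for k, v in comp_covars.items()},
                (t - onset_year[t2d]).astype(float),
            )
        complication = t2d & (streams.prog[:, t] < p_comp)

        state = np.where(died, HealthState.DEAD, state)
        state = np.where(onset, HealthState.T2D, state)
        onset_year = np.where(onset, t, onset_year)
        state = np.where(complication, HealthState.T2D_COMPLICATIONS, state)

        survivors = active & ~died
        medical_year = (
            1 <= t < policy.medical_therapy_years
        ) & (status == InterventionStatus.LIFESTYLE_MEDICAL)
        cost_t = economics.annual_cost(
            state,
            age_t,
            sex,
            params.costs,
            include_productivity=include_productivity,
            medical_this_year=medical_year & survivors,
        )
        util_t = economics.annual_utility(state, age_t, sex, params.utilities)
        df_t = (1.0 + discount_rate) ** (-t)  # cycle t is year t+1
        total_cost += np.where(survivors, cost_t, 0.0) * df_t
        total_qaly += np.where(survivors, util_t, 0.0) * df_t
        years_alive += survivors
        years_t2d_free += survivors & (state == HealthState.HEALTHY)
        years_comp_free += survivors & (state != HealthState.T2D_COMPLICATIONS)

    per_individual = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy() if "id" in cohort else np.arange(n),
            "cost": total_cost,
            "qaly": total_qaly,
            "years_alive": years_alive,
            "years_t2d_free": years_t2d_free,
            "years_complication_free": years_comp_free,
            "final_state": state,
            "intervention_status": status,
        }
    )
    return ArmResult(
        strategy=strategy,
        n=n,
        mean_cost=float(total_cost.mean()),
        mean_qaly=float(total_qaly.mean()),
        mean_years_t2d_free=float(years_t2d_free.mean()),
        mean_years_complication_free=float(years_comp_free.mean()),
        death_fraction=float((state == HealthState.DEAD).mean()),
        reclassified_fraction=reclassification_rate(cohort),
        per_individual=per_individual,
    )


def run_pair(
    cohort: pd.DataFrame,
    models: ModelSet,
    params: ParameterSet,
    policy: InterventionPolicy,
    seed,
    **kwargs,
) -> tuple[ArmResult, ArmResult]:
    """Run both arms on the same cohort with common random numbers."""
    age0 = cohort["age"].to_numpy(dtype=int)
    t_max = int((100 - age0).max())
    horizon = kwargs.get("horizon_years")
    if horizon is not None:
        t_max = min(t_max, int(horizon))
    streams = seed if isinstance(seed, UniformStreams) else draw_streams(len(cohort), t_max, seed)
    usual = run_arm(cohort, Strategy.USUAL, models, params, policy, streams, **kwargs)
    prs = run_arm(cohort, Strategy.PRS, models, params, policy, streams, **kwargs)
    return usual, prs
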