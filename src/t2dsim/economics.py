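"""Annual cost and utility accounting with discounting.

Costs are 2021 euros from a societal perspective (direct non-medical costs
such as travel excluded).  People with T2D accrue annual primary-care,
secondary-care and medication costs; complications add an extra annual
cost; productivity losses apply in both diseased states while the simulated
age is under 65.  Utilities are age-band and sex specific EQ-5D-3L baseline
weights with additive disutilities for T2D and for T2D complications,
floored at zero.

Discounting starts from the second year onward: year 1 is undiscounted and
year ``t`` carries a factor ``(1 + rate)^-(t-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .microsim_engine import HealthState

__all__ = [
    "CostParameters",
    "UtilityParameters",
    "DiscountSpec",
    "annual_cost",
    "annual_utility",
    "discount_factor",
    "aggregate_trajectory",
]

# (lower bound inclusive) -> band key, resolved from current simulated age
AGE_BANDS = ((65, "65+"), (55, "55-64"), (45, "45-54"), (30, "30-44"))


def age_band(age) -> np.ndarray:
    """Map an age (or array of ages) to its utility age band key."""
    age = np.asarray(age)
    out = np.full(age.shape, "30-44", dtype=object)
    for lower, key in AGE_BANDS[:-1][::-1]:
        out[age >= lower] = key
    return out if age.shape else out[()]


@dataclass(frozen=True)
class CostParameters:
    """Annual and one-off cost inputs in euros (2021 price level)."""

    productivity_t2d: float = 7632.0  # per year, while age < 65, both T2D states
    complications_extra: float = 4401.0  # per year on top of T2D costs
    t2d_secondary_care: float = 3315.0  # per year
    medical_therapy_annual: float = 1965.0  # per year while therapy active
    lifestyle_intervention: float = 650.0  # one-off
    prs_test: float = 50.0  # one-off, PRS arm only
    t2d_primary_care_male: float = 562.0  # per year
    t2d_primary_care_female: float = 542.0  # per year
    t2d_medication: float = 584.0  # per year

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"cost parameter {name} must be non-negative")

    def primary_care(self, sex) -> np.ndarray:
        """Sex coded 1 = male, 0 = female."""
        return np.where(
            np.asarray(sex) == 1, self.t2d_primary_care_male, self.t2d_primary_care_female
        )


def _default_baseline_utilities() -> dict[tuple[str, str], float]:
    return {
        ("female", "30-44"): 0.906,
        ("female", "45-54"): 0.865,
        ("female", "55-64"): 0.810,
        ("female", "65+"): 0.770,
        ("male", "30-44"): 0.917,
        ("male", "45-54"): 0.876,
        ("male", "55-64"): 0.821,
        ("male", "65+"): 0.781,
    }


@dataclass(frozen=True)
class UtilityParameters:
    """EQ-5D-3L baseline utilities by (sex, age band) and disease disutilities.

    ``additive_complications`` keeps the default convention that the
    complication disutility adds to the T2D disutility; if False it replaces
    it.
    """

    baseline: Mapping[tuple[str, str], float] = field(
        default_factory=_default_baseline_utilities
    )
    disutility_t2d: float = 0.041
    disutility_complications: float = 0.119
    additive_complications: bool = True

    def __post_init__(self) -> None:
        for key, value in self.baseline.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"baseline utility {key} outside [0, 1]")
        if self.disutility_t2d < 0 or self.disutility_complications < 0:
            raise ValueError("disutilities must be non-negative")

    def baseline_at(self, age, sex) -> np.ndarray:
        """Baseline utility for current age and sex (1 = male, 0 = female)."""
        band_keys = ("30-44", "45-54", "55-64", "65+")
        table = np.array(
            [
                [self.baseline[("female", b)] for b in band_keys],
                [self.baseline[("male", b)] for b in band_keys],
            ]
        )
        age_arr = np.asarray(age)
        band_idx = np.digitize(age_arr, (45, 55, 65))
        out = table[np.asarray(sex, dtype=int), band_idx]
        return out if age_arr.shape else float(out)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied from the second year onward."""

    rate: float = 0.03

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be non-negative")


def annual_cost(
    state,
    age,
    sex,
    params: CostParameters,
    include_productivity: bool = True,
    lifestyle_this_year: bool = False,
    medical_this_year: bool = False,
    prs_test_this_year: bool = False,
) -> np.ndarray:
    """Total cost accrued in one annual cycle, in euros.

    State costs: HEALTHY and DEAD accrue nothing; T2D accrues sex-specific
    primary care + medication + secondary care (+ productivity losses if the
    flag is on and age < 65); T2D with complications adds the extra
    complication cost.  One-off intervention/test charges are added when the
    corresponding flags are set for this cycle.
    """
    state_val = np.asarray(getattr(state, "value", state), dtype=int)
    age = np.asarray(age)
    cost = np.zeros(np.broadcast_shapes(state_val.shape, age.shape))

    t2d_like = (state_val == HealthState.T2D.value) | (
        state_val == HealthState.T2D_COMPLICATIONS.value
    )
    base_t2d = params.primary_care(sex) + params.t2d_medication + params.t2d_secondary_care
    cost = np.where(t2d_like, base_t2d, cost)
    if include_productivity:
        cost = np.where(t2d_like & (age < 65), cost + params.productivity_t2d, cost)
    cost = np.where(
        state_val == HealthState.T2D_COMPLICATIONS.value,
        cost + params.complications_extra,
        cost,
    )
    if np.any(lifestyle_this_year):
        cost = cost + np.asarray(lifestyle_this_year) * params.lifestyle_intervention
    if np.any(medical_this_year):
        cost = cost + np.asarray(medical_this_year) * params.medical_therapy_annual
    if np.any(prs_test_this_year):
        cost = cost + np.asarray(prs_test_this_year) * params.prs_test
    return cost if cost.shape else float(cost)


def annual_utility(state, age, sex, params: UtilityParameters) -> np.ndarray:
    """Utility weight for one annual cycle, floored at zero."""
    state_val = np.asarray(getattr(state, "value", state), dtype=int)
    base = np.asarray(params.baseline_at(age, sex))
    util = np.where(state_val == HealthState.HEALTHY.value, base, 0.0)
    if params.additive_complications:
        comp_du = params.disutility_t2d + params.disutility_complications
    else:
        comp_du = params.disutility_complications
    util = np.where(state_val == HealthState.T2D.value, base - params.disutility_t2d, util)
    util = np.where(
        state_val == HealthState.T2D_COMPLICATIONS.value, base - comp_du, util
    )
    util = np.maximum(util, 0.0)
    util = np.where(state_val == HealthState.DEAD.value, 0.0, util)
    return util if util.shape else float(util)


def discount_factor(year_index, rate: float) -> np.ndarray:
    """Discount multiplier for 1-based cycle ``year_index``.

    Year 1 is undiscounted; year ``t`` is discounted by
    ``(1 + rate)^-(t - 1)``.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    year_index = np.asarray(year_index)
    if np.any(year_index < 1):
        raise ValueError("year_index is 1-based and must be >= 1")
    out = (1.0 + rate) ** (-(year_index - 1.0))
    return out if out.shape else float(out)


def aggregate_trajectory(trajectory, discount: DiscountSpec) -> tuple[float, float]:
    """Total discounted cost and QALYs of one simulated life course.

    ``trajectory`` provides per-year ``cost`` and ``utility`` sequences
    (see :class:`~t2dsim.microsim_engine.Trajectory`).
    """
    costs = np.asarray(trajectory.costs, dtype=float)
    utils = np.asarray(trajectory.utilities, dtype=float)
    if costs.size == 0:
        return 0.0, 0.0
    years = np.arange(1, costs.size + 1)
    df = discount_factor(years, discount.rate)
    return float(np.sum(costs * df)), float(np.sum(utils * df))
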