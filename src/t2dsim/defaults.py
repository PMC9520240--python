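"""Shipped default model coefficients and parameter set.

The original incidence regressions were estimated on restricted registry
data and their coefficients are not public.  The coefficient sets below are
therefore *stipulated synthetic values*: plausible in sign and magnitude,
and calibrated once so that the default synthetic cohort places roughly
10.5% of adults in the 10%-20% 10-year-risk screening band.  They are
configuration data for testing and demonstration, not estimates about any
real population.
"""

from __future__ import annotations

from .survival_models import (
    LifeTable,
    WeibullAFTModel,
    make_synthetic_life_table,
)

__all__ = [
    "DEFAULT_WEIBULL_SHAPE",
    "default_t2d_model_with_prs",
    "default_t2d_model_no_prs",
    "default_complication_model",
    "default_life_table",
]

DEFAULT_WEIBULL_SHAPE = 1.6  # Weibull shape k; AFT scale = 1/k

# AFT log-lambda coefficients: negative = shorter time to T2D = higher risk.
_T2D_COEFS = {"age": -0.015, "sex": -0.15, "findrisc": -0.09}
_PRS_COEF = -0.30  # per standardized PRS unit
_T2D_INTERCEPT = 6.26  # calibrated; see docs/methods.md


def default_t2d_model_with_prs() -> WeibullAFTModel:
    """T2D incidence model with the PRS as an extra covariate.

    This is also the engine's "truth" model: disease onset in both strategy
    arms is driven by it, so genetically higher-risk individuals truly
    progress faster.
    """
    return WeibullAFTModel(
        intercept=_T2D_INTERCEPT,
        coefficients={**_T2D_COEFS, "prs": _PRS_COEF},
        scale=1.0 / DEFAULT_WEIBULL_SHAPE,
    )


def default_t2d_model_no_prs() -> WeibullAFTModel:
    """T2D incidence model without genetic information.

    Approximates a refit without the PRS by dropping the PRS term; since the
    PRS is standardized to mean 0 this matches the with-PRS model at the
    population average.
    """
    return WeibullAFTModel(
        intercept=_T2D_INTERCEPT,
        coefficients=dict(_T2D_COEFS),
        scale=1.0 / DEFAULT_WEIBULL_SHAPE,
    )


def default_complication_model() -> WeibullAFTModel:
    """Time from T2D diagnosis to first major complication (clock reset)."""
    return WeibullAFTModel(
        intercept=3.1,
        coefficients={"sex": -0.10},
        scale=1.0 / 1.3,
    )


def default_life_table() -> LifeTable:
    """Synthetic Gompertz-Makeham all-cause life table (see survival_models)."""
    return make_synthetic_life_table()
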