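import numpy as np
import pytest

from t2dsim.config import RunConfig
from t2dsim.microsim_engine import (
    InterventionPolicy,
    ModelSet,
    ParameterSet,
    draw_streams,
)
from t2dsim.psa_decision import _make_target_cohort
from t2dsim.survival_models import LifeTable, WeibullAFTModel


@pytest.fixture(scope="session")
def models() -> ModelSet:
    return ModelSet.defaults()


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return ParameterSet.base_case()


@pytest.fixture(scope="session")
def policy() -> InterventionPolicy:
    return InterventionPolicy()


@pytest.fixture(scope="session")
def target_cohort(models):
    """Small screening-band cohort shared across engine tests."""
    config = RunConfig(seed=11, n_per_arm=400)
    return _make_target_cohort(config, models, 400, seed=11)


@pytest.fixture(scope="session")
def shared_streams(target_cohort):
    t_max = int((100 - target_cohort["age"].to_numpy(dtype=int)).max())
    return draw_streams(len(target_cohort), t_max, 202)


@pytest.fixture(scope="session")
def zero_life_table() -> LifeTable:
    n = LifeTable.AGE_MAX - LifeTable.AGE_MIN + 1
    return LifeTable(np.zeros(n), np.zeros(n))


@pytest.fixture(scope="session")
def null_hazard_model() -> WeibullAFTModel:
    """Event time pushed far beyond any horizon: annual probabilities are 0."""
    return WeibullAFTModel(intercept=50.0, coefficients={}, scale=1.0)
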