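import numpy as np
import pytest

from medlysim import ModelParameters, generate_cohort
from medlysim.scenarios import assign_deployment


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def short_params() -> ModelParameters:
    """Reference parameters on a 5-year horizon for fast engine tests."""
    p = ModelParameters()
    p.horizon_months = 60
    return p


@pytest.fixture
def small_cohort(short_params):
    cohort = generate_cohort(40, params=short_params, seed=11)
    return assign_deployment(cohort, short_params.deployment_ratio, seed=11)


@pytest.fixture
def null_intervention(short_params) -> ModelParameters:
    """Treatment arm with no effect and no program costs."""
    p = short_params.copy()
    p.rr_mortality = 1.0
    p.rr_hospitalization = 1.0
    p.medly_fixed_site_cost = 0.0
    p.medly_operational_monthly = 0.0
    p.kit_monthly_cost = {"FK": 0.0, "BYOP": 0.0, "BYOE": 0.0}
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
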