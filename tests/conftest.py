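import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shallowlake.lake import LakeParams
from shallowlake.strategies import make_high_emissions_stepwise, make_low_emissions
from shallowlake.synthetic import (
    PriorSpec,
    generate_observations,
    generate_truth,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_params() -> LakeParams:
    return LakeParams(b=0.42, q=2.0)


@pytest.fixture(scope="session")
def low_schedule(truth_params):
    return make_low_emissions(truth_params, T=100)


@pytest.fixture(scope="session")
def high_schedule(truth_params):
    return make_high_emissions_stepwise(truth_params, T=100)


@pytest.fixture(scope="session")
def low_truth(low_schedule):
    return generate_truth(low_schedule)


@pytest.fixture(scope="session")
def high_truth(high_schedule):
    return generate_truth(high_schedule)


@pytest.fixture(scope="session")
def high_obs(high_truth):
    return generate_observations(high_truth, seed=11)


@pytest.fixture(scope="session")
def low_obs(low_truth):
    return generate_observations(low_truth, seed=11)


@pytest.fixture(scope="session")
def prior_spec():
    return PriorSpec.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
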