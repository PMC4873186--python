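import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stereobem.experiments import decision_population

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def static_pop():
    """The 160-cell decision population with static receptive fields."""
    return decision_population(kernel_kind=None)


@pytest.fixture(scope="session")
def temporal_pop():
    """The 160-cell decision population with the biphasic temporal kernel."""
    return decision_population()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
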