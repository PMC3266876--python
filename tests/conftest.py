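import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wormrepro import ObservationProtocol, PopulationParams, default_law, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pp():
    return PopulationParams()


@pytest.fixture(scope="session")
def law():
    return default_law()


@pytest.fixture(scope="session")
def small_proto():
    return ObservationProtocol(n_longitudinal=30, n_per_dense_timepoint=4)


@pytest.fixture(scope="session")
def cohort20(pp, law, small_proto):
    return simulate_cohort(pp, law, 20.0, small_proto, seed=11)


@pytest.fixture(scope="session")
def cohort29(pp, law, small_proto):
    return simulate_cohort(pp, law, 29.0, small_proto, seed=12)
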