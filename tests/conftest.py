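import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from casemix.elixhauser import load_definitions
from casemix.synthetic import GeneratorConfig, generate_records

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def definitions():
    return load_definitions()


@pytest.fixture(scope="session")
def cohort_20k():
    """Mid-sized raw synthetic cohort shared across rate/label/round-trip tests."""
    cfg = GeneratorConfig(n=20_000, seed=1)
    return generate_records(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = GeneratorConfig(n=300, seed=2)
    return generate_records(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
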