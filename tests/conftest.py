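import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bodycomp3c.synthetic_cohort import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A study-sized cohort (n=40) with a fixed seed."""
    return generate_cohort(CohortConfig(n=40, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """A cohort large enough for stable moment checks."""
    return generate_cohort(CohortConfig(n=100_000, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
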