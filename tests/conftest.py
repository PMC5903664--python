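import numpy as np
import pytest
from hypothesis import settings

from wheezesev import SimConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate synthetic cohort shared by read-only tests."""
    return generate_cohort(SimConfig(n=2000, seed=101))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for tests of population-level structure."""
    return generate_cohort(SimConfig(n=100_000, seed=202))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
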