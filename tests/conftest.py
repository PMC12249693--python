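import pytest
from hypothesis import settings

from uhrisk import CohortConfig, generate_cohort

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(n_subjects=132, seed=7)


@pytest.fixture(scope="session")
def cohort132(default_config):
    """One default-size cohort shared across read-only tests."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort for marginal-fidelity and recovery checks."""
    return generate_cohort(CohortConfig(n_subjects=5000, seed=11))
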