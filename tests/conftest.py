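import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 150-patient cohort shared across tests."""
    from cmslike import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_patients=150, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
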