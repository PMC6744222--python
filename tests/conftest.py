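import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort at default study conditions, shared across tests."""
    from pogdiv import CohortSpec, simulate_cohort

    return simulate_cohort(CohortSpec(n_genes=300, n_codons=300, seed=123))
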