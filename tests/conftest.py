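import pytest
from hypothesis import HealthCheck, settings

from promediate import CohortConfig, MCMCConfig, MediationParams, extract_cohort, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return MediationParams()


@pytest.fixture(scope="session")
def quick_mcmc():
    """Small but valid sampler settings for unit tests."""
    return MCMCConfig(n_chains=2, n_draws=800, n_burn_in=300, seed=5)


@pytest.fixture(scope="session")
def small_table():
    """A rendered-and-extracted cohort of 40 subjects under default truth."""
    cfg = CohortConfig(n_subjects=40, seed=11)
    transcripts, _ = simulate_cohort(cfg)
    return extract_cohort(transcripts)
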