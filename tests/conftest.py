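import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from audiosem.cohort import CohortConfig, generate_cohort
from audiosem.features import FeatureConfig
from audiosem.rules import default_rule_base


@pytest.fixture(scope="session")
def config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def rule_base(config):
    return default_rule_base(config)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """500 patients without measurement noise: truth is unambiguous."""
    return generate_cohort(CohortConfig(n_patients=500, seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """300 patients at the default 5 dB measurement noise."""
    return generate_cohort(CohortConfig(n_patients=300, seed=7, noise_sd=5.0))
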