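import numpy as np
import pytest

from dietclust import DPMConfig, GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (n = 5,396), generated once per session."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for faster tests."""
    return generate_cohort(GeneratorConfig(seed=5, n_participants=800))


@pytest.fixture
def fast_dpm_config():
    return DPMConfig(truncation_K=8, n_burnin=200, n_samples=800, seed=7)
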