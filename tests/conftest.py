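import numpy as np
import pytest

from dyncouple import SimConfig
from dyncouple.synth import simulate_eeg, simulate_latent_state, simulate_study


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Two subjects per group keeps whole-study tests fast."""
    return SimConfig(n_subjects_per_group=2, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    return simulate_study(small_sim_config)


@pytest.fixture(scope="session")
def latent306():
    return simulate_latent_state(306, 0.02, 1.8, seed=42)


@pytest.fixture(scope="session")
def default_eeg(latent306):
    return simulate_eeg(latent306, SimConfig(), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
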