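import numpy as np
import pytest

from rotordetect.catheter import build_layout
from rotordetect.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free simulation settings (no far field, no mains)."""
    return SimConfig(noise_sd=0.0, farfield_amplitude=0.0, seed=123)


@pytest.fixture(scope="session")
def small_cohort(clean_config):
    """Six noiseless acquisitions (3 patients) with ground truth."""
    return simulate_cohort(clean_config, 3, 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
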