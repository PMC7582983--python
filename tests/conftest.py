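import numpy as np
import pytest
from hypothesis import settings

from bcgsleep import BcgSimSpec, simulate_bcg
from bcgsleep.staging import load_reference_params

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_params():
    return load_reference_params()


@pytest.fixture(scope="session")
def clean_sim():
    """Short noise-free simulated recording with ground-truth beats."""
    return simulate_bcg(BcgSimSpec(duration=120.0, snr_db=None, hr_sd=2.0, seed=11))


@pytest.fixture(scope="session")
def noisy_sim():
    """Ten-minute recording at 10 dB SNR: the end-to-end study condition."""
    return simulate_bcg(BcgSimSpec(duration=600.0, mean_hr=60.0, hr_sd=5.0, snr_db=10.0, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
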