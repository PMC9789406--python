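import numpy as np
import pytest

from depthgait.synth import TrialSpec, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free default trial shared across tests (read-only)."""
    return generate_trial(TrialSpec(duration=3.0, seed=0))


@pytest.fixture(scope="session")
def noisy_trial():
    """Trial with 1% BL landmark jitter."""
    return generate_trial(TrialSpec(duration=3.0, seed=0, noise_sd=0.01))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
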