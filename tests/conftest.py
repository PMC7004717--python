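import numpy as np
import pytest

from cai import DepthProfile, SimConfig, simulate_eeg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def awake_record():
    """60 s of simulated awake (d=0) EEG."""
    rec, _ = simulate_eeg(DepthProfile([0, 60], [0.0, 0.0]), SimConfig(seed=11))
    return rec


@pytest.fixture(scope="session")
def deep_record():
    """60 s of simulated deep (d=0.9) burst-suppression EEG."""
    rec, _ = simulate_eeg(DepthProfile([0, 60], [0.9, 0.9]), SimConfig(seed=12))
    return rec
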