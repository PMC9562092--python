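import numpy as np
import pytest

from eegdecide.synth import SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Four blocks of 4 trials; full channel set, default noise."""
    return SynthConfig(trials_per_block=4, seed=99)


@pytest.fixture(scope="session")
def tiny_recording(tiny_config):
    return generate_recording(tiny_config)


@pytest.fixture(scope="session")
def noisefree_config():
    return SynthConfig(trials_per_block=3, noise_scale=0.0, seed=5)


@pytest.fixture(scope="session")
def noisefree_recording(noisefree_config):
    return generate_recording(noisefree_config)
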