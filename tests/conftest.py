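import numpy as np
import pytest

from stresskit import SynthConfig, generate_library
from stresskit.nn import CNNConfig


@pytest.fixture(scope="session")
def small_library():
    """60-sample labeled library on the full 437-2345 nm grid."""
    return generate_library(SynthConfig(n_per_class=10, seed=11))


@pytest.fixture(scope="session")
def noiseless_library():
    """Noise-free library: class means are exact severity responses."""
    return generate_library(SynthConfig(n_per_class=4, noise_sd=0.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_cnn_config():
    """Small network for unit tests; full defaults are exercised in acceptance."""
    return CNNConfig(f1=8, f2=16, epochs=30, learning_rate=0.01, batch_size=32, seed=0)
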