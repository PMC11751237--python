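import numpy as np
import pytest

from m3bnet.phantom import PhantomParams, generate_pair


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def sample_pair(default_params):
    """One rendered phantom pair with default (noisy, unevenly lit) settings."""
    return generate_pair(default_params, rng_seed=42)


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, evenly lit pair: intensities take exactly two levels."""
    params = PhantomParams(noise_sigma=0.0, illum_amplitude=0.0)
    return generate_pair(params, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
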