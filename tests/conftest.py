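import numpy as np
import pytest

from ricianet import ArchConfig, NoiseSpec, generate_phantom, rician_corrupt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 piecewise-constant phantom used by several suites."""
    return generate_phantom((32, 32, 32), seed=7)


@pytest.fixture(scope="session")
def smooth_phantom():
    return generate_phantom((64, 64, 64), seed=11, smooth_sigma=0.8)


@pytest.fixture(scope="session")
def noisy_pair(smooth_phantom):
    clean = smooth_phantom.intensity
    spec = NoiseSpec.for_volume(clean, level_percent=9.0, seed=100)
    return rician_corrupt(clean, spec)


@pytest.fixture()
def tiny_2d_config():
    return ArchConfig(dim=2, n_modules=2, filters=4, dilation_schedule=(1, 2))
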