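import numpy as np
import pytest

from dpvesselsynth import phantoms


@pytest.fixture(scope="session")
def small_volume():
    """One deterministic phantom volume shared across tests."""
    return phantoms.generate_volume(seed=7, shape=(64, 64, 32), n_vessels=4, noise_level=0.05)


@pytest.fixture(scope="session")
def small_patches(small_volume):
    """A deterministic labeled patch set (32 x 32) from the shared volume."""
    return phantoms.extract_patches(
        small_volume, n_vessel_centered=30, n_random=30, patch_size=32, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
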