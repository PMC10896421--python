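import numpy as np
import pytest

from cryoredox import PhantomParams, generate_phantom_stack


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with identity optics: recoverable exactly."""
    params = PhantomParams(shape=(10, 40, 40), noise_sd=0.0, dark_level=0.0,
                           vignette_strength=1.0, brightness_cv=0.0,
                           voxel_rr_cv=0.0, seed=11)
    return generate_phantom_stack(params)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at default imaging conditions (vignette, dark, read noise)."""
    params = PhantomParams(shape=(12, 48, 48), seed=23, voxel_rr_cv=0.2)
    return generate_phantom_stack(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
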