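import numpy as np
import pytest

from meatwhc import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Small noise-free phantom with no texture: closed forms are exact."""
    return PhantomSpec(image_size=64, noise_sd=0.0, texture_amplitude=0.0,
                       response_noise_sd=0.0, clip_fraction=0.0, seed=7)


@pytest.fixture
def small_spec():
    """Small phantom at default noise/texture for integration-style tests."""
    return PhantomSpec(image_size=64, seed=7)
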