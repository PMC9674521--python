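import numpy as np
import pytest

from noise2fast import Image2D, add_gaussian_noise, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def blobs_phantom():
    return make_phantom("blobs", (64, 64), seed=7)


@pytest.fixture
def noisy_blobs(blobs_phantom):
    return add_gaussian_noise(blobs_phantom.clean, sigma=25.0, seed=7)


@pytest.fixture
def small_image(rng):
    return Image2D(rng.uniform(0, 255, size=(16, 20)))
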