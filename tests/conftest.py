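import numpy as np
import pytest

from biofilmtex import GreyImage, simulate_micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shem_native():
    """One fixed native-condition SHeM-profile micrograph (400x400)."""
    image, truth = simulate_micrograph("native", "shem", seed=1)
    return image, truth


@pytest.fixture(scope="session")
def small_shem_native(shem_native):
    """A 160x160 crop of the native SHeM image, for windowed tests."""
    image, _ = shem_native
    return GreyImage(image.pixels[:160, :160], image.pixel_size)


def random_grey(rng, shape=(16, 16), low=0, high=256):
    """A random integer-valued greyscale test image."""
    return GreyImage(rng.integers(low, high, shape).astype(float))
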