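import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 phantom with a couple of vessels; shared across tests."""
    from vesselseg import PhantomSpec, generate_phantom

    spec = PhantomSpec(height=64, width=64, n_vessels=2,
                       vessel_width_range=(2, 5), seed=11)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def stripe_image():
    """Dark horizontal stripe (width 5, contrast 60) on a flat background."""
    from vesselseg import IntensityImage

    pixels = np.full((61, 61), 180.0)
    pixels[28:33, :] = 120.0
    return IntensityImage(pixels)
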