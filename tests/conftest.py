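import numpy as np
import pytest

from tatha.synth import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom64():
    """One reproducible 64x64 phantom with a single nodule."""
    return generate_phantom(PhantomSpec(size=64, axis_range=(8, 16), seed=3))


@pytest.fixture(scope="session")
def speckled_flat():
    """A 64x64 flat field with multiplicative speckle, no nodule."""
    rng = np.random.default_rng(9)
    return np.clip(0.5 * rng.gamma(4.0, 0.25, size=(64, 64)), 0, 1)
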