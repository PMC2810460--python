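import numpy as np
import pytest

from mcdetect.imagery import GrayImage
from mcdetect.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def fatty_phantom():
    """One fixed fatty phantom with 3 planted clusters (image, truth, ann)."""
    return generate_phantom(PhantomSpec(tissue="fatty", seed=314))


@pytest.fixture(scope="session")
def dense_phantom():
    return generate_phantom(PhantomSpec(tissue="dense", seed=271))


@pytest.fixture()
def random_image():
    """Random 8-bit 64x64 image (fresh generator per test)."""
    rng = np.random.default_rng(2024)
    return GrayImage(rng.integers(0, 256, size=(64, 64)).astype(float))
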