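import numpy as np
import pytest

from ctpcodec import DynamicImage, PhantomSpec, compress, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A seeded default-schedule phantom small enough for exhaustive checks."""
    img, labels = generate_phantom(PhantomSpec(shape=(2, 32, 32), seed=7))
    return img, labels


@pytest.fixture(scope="session")
def small_phantom_compressed(small_phantom):
    img, _ = small_phantom
    return compress(img)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(rng, n, shape, extremes=True):
    """A random 16-bit dynamic image; extreme values included by default."""
    data = rng.integers(-32768, 32768, size=(n, *shape), dtype=np.int16)
    if extremes and data.size >= 4:
        flat = data.reshape(-1)
        pos = rng.choice(flat.size, size=4, replace=False)
        flat[pos[:2]] = -32768
        flat[pos[2:]] = 32767
    return DynamicImage(data)
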