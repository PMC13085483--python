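import numpy as np
import pytest

from mammoseg.phantom import ImagePair, PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_512():
    """One 512-px phantom with a medium lesion, shared across tests."""
    return generate_phantom(PhantomConfig(
        image_side=512, n_lesions=1, lesion_areas=(2000,), seed=7))


@pytest.fixture(scope="session")
def phantom_small_lesion():
    return generate_phantom(PhantomConfig(
        image_side=512, n_lesions=1, lesion_areas=(300,), seed=8))


@pytest.fixture
def square_pair():
    """Deterministic hand-built pair: 100x100 solid lesion in 1000x1000."""
    img = np.full((1000, 1000), 0.3, dtype=np.float32)
    msk = np.zeros((1000, 1000), dtype=np.uint8)
    msk[450:550, 450:550] = 1
    img[450:550, 450:550] = 0.7
    return ImagePair(id="square", image=img, mask=msk, native_side=1000)


def random_binary_mask(rng, shape=(32, 32), p=0.2):
    return (rng.random(shape) < p).astype(np.uint8)
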