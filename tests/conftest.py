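import numpy as np
import pytest

from sonotex.image import GrayImage
from sonotex.synthetic import class_preset, generate_liver_image


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """Unmasked random 32x32 8-bit image."""
    return GrayImage(rng.integers(0, 256, size=(32, 32), dtype=np.uint8))


@pytest.fixture
def masked_random_image(rng):
    """Random 32x32 image with an irregular ~60%-coverage mask."""
    pixels = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
    mask = rng.random((32, 32)) < 0.6
    mask[16, 16] = True  # never empty
    return GrayImage(pixels, mask)


@pytest.fixture
def liver_case():
    """One synthetic normal-liver case with its ground-truth polygon mask."""
    return generate_liver_image(class_preset("normal", seed=7))


def seeded_images(n, shape=(32, 32), mask_fraction=None, seed=0):
    """n seeded random GrayImages, optionally with random masks."""
    rng = np.random.default_rng(seed)
    images = []
    for _ in range(n):
        pixels = rng.integers(0, 256, size=shape, dtype=np.uint8)
        mask = None
        if mask_fraction is not None:
            mask = rng.random(shape) < mask_fraction
            mask[shape[0] // 2, shape[1] // 2] = True
        images.append(GrayImage(pixels, mask))
    return images
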