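import numpy as np
import pytest

from fcamseg import build_palette

RED = (220, 40, 40)
GREEN = (40, 200, 40)
BLUE = (40, 40, 220)


@pytest.fixture
def palette222_crisp():
    return build_palette((2, 2, 2), "crisp")


@pytest.fixture
def palette242_gauss():
    return build_palette((2, 4, 2), "gaussian")


@pytest.fixture
def toy3x3():
    """3x3 image: blue center surrounded by green."""
    img = np.empty((3, 3, 3), dtype=np.uint8)
    img[...] = GREEN
    img[1, 1] = BLUE
    return img


def random_palette_image(rng, palette, shape=(8, 8)):
    """Image whose colors are all palette centers."""
    idx = rng.integers(0, palette.n_colors, size=shape)
    return palette.centers[idx].astype(np.uint8)
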