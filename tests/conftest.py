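import numpy as np
import pytest

from shellfeat.imaging_core import (
    CANONICAL_HEIGHT,
    CANONICAL_WIDTH,
    ShellImage,
    ShellMask,
)
from shellfeat.synthetic_shells import generate_dataset


def black_frame() -> np.ndarray:
    return np.zeros((CANONICAL_HEIGHT, CANONICAL_WIDTH, 3), dtype=np.uint8)


def rect_image(top=150, left=100, h=100, w=100, colour=(255, 255, 255)) -> ShellImage:
    """A solid rectangle on a pure-black canonical frame."""
    px = black_frame()
    px[top: top + h, left: left + w] = colour
    return ShellImage(px)


def disc_mask(radius: float, shape=(CANONICAL_HEIGHT, CANONICAL_WIDTH),
              centre=None) -> ShellMask:
    h, w = shape
    cy, cx = centre if centre else ((h - 1) / 2.0, (w - 1) / 2.0)
    y, x = np.mgrid[0:h, 0:w]
    return ShellMask(np.hypot(x - cx, y - cy) <= radius)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 species x 3 samples, in memory — enough for integration tests."""
    return generate_dataset(3, 3, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions: 10 species x 10 samples."""
    return generate_dataset(10, 10, seed=2026)


@pytest.fixture(scope="session")
def gabor_bank():
    from shellfeat.texture_features import build_bank

    return build_bank()
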