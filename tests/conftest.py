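import numpy as np
import pytest
from PIL import Image

from leafskew.imaging import LeafImage


@pytest.fixture
def rgba_png(tmp_path):
    """Factory writing a small RGBA PNG from explicit pixel arrays."""

    def make(rgb: np.ndarray, alpha: np.ndarray, name: str = "leaf.png"):
        h, w, _ = rgb.shape
        arr = np.dstack([rgb.astype(np.uint8), alpha.astype(np.uint8)])
        path = tmp_path / name
        Image.fromarray(arr, mode="RGBA").save(path)
        return path

    return make


@pytest.fixture
def rgb_png(tmp_path):
    """Factory writing a small flat RGB PNG."""

    def make(rgb: np.ndarray, name: str = "flat.png"):
        path = tmp_path / name
        Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(path)
        return path

    return make


@pytest.fixture
def uniform_leaf():
    """Factory for an in-memory LeafImage with constant channel values."""

    def make(r: int, g: int, b: int, shape=(4, 5), mask=None):
        full = np.ones(shape, dtype=np.uint8)
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        return LeafImage(red=full * r, green=full * g, blue=full * b, mask=mask)

    return make
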