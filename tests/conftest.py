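import numpy as np
import pytest
from hypothesis import settings
from PIL import Image

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def write_png(tmp_path):
    """Write an (H, W, 3) uint8 array to a PNG and return the path."""

    def _write(array, name="image.png"):
        path = tmp_path / name
        Image.fromarray(np.asarray(array, dtype=np.uint8)).save(path)
        return path

    return _write


@pytest.fixture
def gray_image():
    """A 10x10 uniform gray image (r = g = b = 120): zero vegetation."""
    return np.full((10, 10, 3), 120, dtype=np.uint8)
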