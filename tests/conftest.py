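import numpy as np
import pytest

from fnfpepper import GeneratorConfig, RGBImage, hsv_to_rgb, simulate_scenes
from fnfpepper.imaging import HSVImage


def uniform_image(value, height=4, width=4):
    return RGBImage(np.full((height, width, 3), value, dtype=np.uint8))


def disk_image(radius, hue, sat, val=200, size=(240, 320), center=None):
    """RGB image with one HSV-colored disk on a black background."""
    h, w = size
    cy, cx = center or (h // 2, w // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    hsv = HSVImage(
        hue=np.where(mask, float(hue), 0.0),
        saturation=np.where(mask, float(sat), 0.0),
        value=np.where(mask, float(val), 0.0),
    )
    return hsv_to_rgb(hsv), mask


@pytest.fixture(scope="session")
def default_scenes_50():
    """50 default-condition synthetic scenes, shared across evaluation tests."""
    return simulate_scenes(GeneratorConfig(), 50, master_seed=1)
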