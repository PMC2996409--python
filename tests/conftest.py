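import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmapunch import ReferenceProfile

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def profile() -> ReferenceProfile:
    return ReferenceProfile()


@pytest.fixture
def three_patch_image() -> np.ndarray:
    """60x90 image of three uniform gray patches at 235 / 175 / 100."""
    img = np.zeros((60, 90, 3), dtype=np.uint8)
    img[:, :30] = 235
    img[:, 30:60] = 175
    img[:, 60:] = 100
    return img


#: palette of the three-tone segmentation fixtures
WHITE_TONE = (235, 235, 235)
PINK_TONE = (230, 180, 200)
BLUE_TONE = (90, 90, 160)


@pytest.fixture
def three_tone_tile() -> np.ndarray:
    """Tile of three uniform vertical bands: white, pink, blue."""
    img = np.zeros((60, 90, 3), dtype=np.uint8)
    img[:, :30] = WHITE_TONE
    img[:, 30:60] = PINK_TONE
    img[:, 60:] = BLUE_TONE
    return img
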