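import numpy as np
import pytest

from phenovol import synthplant as sp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def growth_config():
    return sp.GrowthConfig()


@pytest.fixture
def camera():
    return sp.CameraConfig()


@pytest.fixture
def small_camera():
    """Small frame for fast render tests on small plants."""
    return sp.CameraConfig(image_width=192, image_height=144, pixel_scale=0.25)


@pytest.fixture
def fixture_rosette():
    """A fixed small rosette (no randomness) used across render tests."""
    leaves = tuple(
        sp.Leaf(length=8.0, max_width=3.6, thickness=1.7,
                inclination=inc, azimuth=az)
        for inc, az in [(55, 0), (55, 72), (55, 144), (55, 216), (55, 288),
                        (30, 36), (30, 156), (30, 276)]
    )
    return sp.PlantShapeModel(leaves, pot_height=6.0, pot_radius=4.0,
                              voxel_pitch=0.17)


def disc_mask(shape, center_row, center_col, radius_px):
    """Filled disc test mask."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_row) ** 2 + (cc - center_col) ** 2 <= radius_px**2


def iou(a, b):
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    return 1.0 if union == 0 else np.logical_and(a, b).sum() / union
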