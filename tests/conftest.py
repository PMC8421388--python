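import numpy as np
import pytest

from gedipipe import (
    FrameImage,
    PlateConfig,
    SensorSpec,
    WellSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def gcamp_like():
    """Activity-sensor stand-in: Kd inside the physiological transient range."""
    return SensorSpec("gcamp-like", kd=375e-9, hill_n=2.3, f_min=0.0, f_max=1.0)


@pytest.fixture
def gedi_like():
    """Death-sensor stand-in: Kd far above physiological transient peaks."""
    return SensorSpec("gedi-like", kd=560e-6, hill_n=1.8, f_min=0.0, f_max=1.0)


@pytest.fixture
def small_plate_config():
    """A small, quick-to-render plate: 2 wells, 3 timepoints, 12 neurons."""
    return PlateConfig(
        wells=[
            WellSpec("A1", "control", 6, 0.01),
            WellSpec("B1", "disease", 6, 0.05),
        ],
        timepoints=(0.0, 24.0, 48.0),
        image_shape=(260, 260),
        min_spacing_px=42.0,
        seed=11,
    )


def disk_image(shape, disks, background=0.0):
    """Paint filled disks (cx, cy, radius, value) onto a background."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy, r, v in disks:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = v
    return img


@pytest.fixture
def make_disk_frame():
    def _make(shape=(100, 100), disks=(), background=0.0, **meta):
        return FrameImage(disk_image(shape, disks, background), **meta)

    return _make
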