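import numpy as np
import pytest

from suvkit.image_model import QuantVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_suv(values, spacing=(4.8, 4.8, 4.8), modality="PET"):
    return QuantVolume(np.asarray(values, dtype=float), spacing, "SUV", modality=modality)


def hot_sphere(shape, spacing, center_mm, radius_mm, hot, background):
    """Binary hot sphere rasterized by voxel-center membership."""
    arr = np.full(shape, float(background))
    xs = (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = (np.arange(shape[2]) + 0.5) * spacing[2]
    d2 = (
        (xs[:, None, None] - center_mm[0]) ** 2
        + (ys[None, :, None] - center_mm[1]) ** 2
        + (zs[None, None, :] - center_mm[2]) ** 2
    )
    arr[d2 <= radius_mm**2] = float(hot)
    return arr


@pytest.fixture
def make_suv_volume():
    return make_suv


@pytest.fixture
def make_hot_sphere():
    return hot_sphere
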