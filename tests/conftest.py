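import numpy as np
import pytest

from batcsi.core import RawImageMatrix, RoiMask, make_roi_mask
from batcsi.phantom import PhantomParams


@pytest.fixture
def small_params():
    """Phantom geometry small enough for fast per-test generation."""
    return PhantomParams(
        image_height=64,
        image_width=64,
        prostate_center=(32, 32),
        prostate_radii=(10, 12),
        annulus_width=8,
        noise_sd=0.0,
        bat_blob_count=0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_pair(water_vals, fat_vals):
    """Wrap plain arrays as a (water, fat) channel pair."""
    return (
        RawImageMatrix(np.asarray(water_vals), "water"),
        RawImageMatrix(np.asarray(fat_vals), "fat"),
    )


def full_mask(shape) -> RoiMask:
    return make_roi_mask(np.ones(shape, dtype=bool))
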