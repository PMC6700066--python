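from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from semsr.images import SEMImage


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def textured_image(shape=(128, 128), pixel_size_nm=7.1, seed=0, scale=3.0) -> SEMImage:
    """Smooth random texture with enough structure for correlation-based
    alignment; values roughly in [0, 1]."""
    r = np.random.default_rng(seed)
    noise = r.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min())
    return SEMImage(smooth, pixel_size_nm)


@pytest.fixture
def texture() -> SEMImage:
    return textured_image()
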