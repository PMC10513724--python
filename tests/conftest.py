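"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

import fgscheck as f


@pytest.fixture
def usaf_image():
    """Noiseless in-focus render of the 1.0 lp/mm element at 10 px/mm."""
    img, gt = f.render_usaf([(0, 1)], px_per_mm=10.0, seed=0)
    return img, gt


@pytest.fixture
def sharpness_render():
    """Noiseless render of the full nine-element sharpness ladder."""
    from fgscheck.resolution import SHARPNESS_ELEMENTS

    img, gt = f.render_usaf(SHARPNESS_ELEMENTS, px_per_mm=40.0, seed=0)
    return img, gt


@pytest.fixture
def conc_panel():
    """Default noiseless concentration plate and its layout."""
    img, gt = f.render_wells("conc", seed=0)
    return img, gt


@pytest.fixture
def depth_panel():
    """Default noiseless depth plate and its layout."""
    img, gt = f.render_wells("depth", seed=0)
    return img, gt


def constant_image(value=1000.0, shape=(64, 64), bit_depth=16):
    return f.Image2D(
        pixels=np.full(shape, float(value)), bit_depth=bit_depth, source="test:constant"
    )
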