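"""Shared fixtures: a compact synthetic retina for fast tests.

The test geometry is a 960 um arena (128 x 128 display pixels of 7.5 um)
with RF centers at its middle, small enough that image generation and LN
fits run in seconds while preserving all spatial relationships.
"""

import numpy as np
import pytest

from rgcspatial.rf_estimation import ParametricRF
from rgcspatial.synthetic import generate_natural_like_images, make_phenotype

ARENA_UM = 960.0
IMG_PX = 128


def small_rf(sigma_um: float = 60.0) -> ParametricRF:
    return ParametricRF(
        center_mean=np.array([ARENA_UM / 2, ARENA_UM / 2]),
        center_cov=np.diag([sigma_um**2, sigma_um**2]),
        surround_strength=0.0,
        surround_scale=2.0,
    )


def small_cell(name: str, **kw):
    cell = make_phenotype(name, rf_params=small_rf(), **kw)
    cell.arena_um = ARENA_UM
    return cell


@pytest.fixture(scope="session")
def images_small():
    """200 natural-like contrast images on the compact arena."""
    return generate_natural_like_images(200, IMG_PX, seed=42).images


@pytest.fixture(scope="session")
def linear_cell():
    return small_cell("linear_on")


@pytest.fixture(scope="session")
def rectified_cell():
    return small_cell("rectified_on")
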