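"""Shared fixtures for the stormsim test suite."""

import numpy as np
import pytest

from stormsim.camera import CameraConfig
from stormsim.optics import OpticalConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def camera16():
    return CameraConfig(sensor_size=(16, 16))


@pytest.fixture
def gaussian_optics():
    return OpticalConfig(psf_model="gaussian")


@pytest.fixture
def scalar_optics():
    return OpticalConfig(psf_model="scalar")


@pytest.fixture
def matched_scalar_optics():
    """Scalar model with matched refractive indices (symmetric limit)."""
    return OpticalConfig(
        psf_model="scalar",
        NA=1.2,
        n_immersion=1.33,
        n_sample=1.33,
        depth_aberration_nm=0.0,
    )
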