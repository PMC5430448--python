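"""Pixel binning, structured background and the EMCCD noise chain.

The photon-valued sub-pixel canvas produced by the optics module is block-
summed to camera pixels, background photon rates are added, and the image is
passed through a standard EMCCD model:

    electrons  ~ Poisson(QE * photons)
    amplified  ~ Gamma(shape = electrons, scale = em_gain)   (0 stays 0)
    ADU        = amplified * adu_per_electron + Normal(0, readout) * adu_per_electron
    output     = clip(round(ADU + baseline), 0, saturation)

The Gamma law is the usual continuous approximation of the electron-
multiplication cascade, accurate for gains much larger than one; it carries
the excess-noise factor of 2.  Setting ``em_gain = 1`` together with
``em_register = False`` gives a plain CCD (Poisson + Gaussian) chain.

Structured fluorescence background (SFB) models defocused fluorescence from
labelled structure above/below the imaged section: the sum image of all
fluorophores is blurred with the PSF at a chosen defocus and rescaled so
that its brightest pixel is a set fraction of the brightest pixel a single
average molecule can produce.  The rate map is static across frames; each
frame draws Poisson photons around it through the camera chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CameraConfig",
    "BackgroundSpec",
    "bin_to_pixels",
    "build_structured_background",
    "apply_camera_noise",
    "single_molecule_peak",
]


@dataclass(frozen=True)
class CameraConfig:
    pixel_size: float = 100.0  # nm in the sample plane
    sensor_size: tuple[int, int] = (64, 64)  # (rows, cols)
    quantum_efficiency: float = 0.9
    em_gain: float = 100.0
    readout_noise_sigma: float = 1.0  # electrons (post-register referred)
    baseline: float = 100.0  # ADU
    adu_per_electron: float = 0.05
    saturation: int = 65535
    em_register: bool = True  # False: plain CCD chain (no Gamma stage)

    def __post_init__(self):
        if min(self.pixel_size, self.quantum_efficiency, self.em_gain,
               self.adu_per_electron) <= 0:
            raise ValueError("camera parameters must be positive")
        if self.quantum_efficiency > 1:
            raise ValueError("quantum_efficiency must be <= 1")
        if self.readout_noise_sigma < 0:
            raise ValueError("readout_noise_sigma must be >= 0")
        if not 0 <= self.baseline < self.saturation:
            raise ValueError("require 0 <= baseline < saturation")

    @property
    def adu_per_photon(self) -> float:
        """Mean ADU (above baseline) produced per incident photon."""
        gain = self.em_gain if self.em_register else 1.0
        return self.quantum_efficiency * gain * self.adu_per_electron


@dataclass(frozen=True)
class BackgroundSpec:
    uniform_rate: float = 0.0  # photons / pixel / frame
    sfb_strength: float = 0.0  # fraction of the single-molecule peak
    sfb_defocus: float = 800.0  # nm

    def __post_init__(self):
        if self.uniform_rate < 0 or self.sfb_strength < 0:
            raise ValueError("background rates must be >= 0")


def bin_to_pixels(canvas: np.ndarray, cfg: CameraConfig,
                  oversampling: int | None = None) -> np.ndarray:
    """Block-sum the sub-pixel canvas to camera pixels (photons conserved)."""
    rows, cols = canvas.shape
    if oversampling is None:
        r = rows // cfg.sensor_size[0]
        if r * cfg.sensor_size[0] != rows:
            raise ValueError("canvas is not an integer multiple of the sensor")
        oversampling = r
    if rows % oversampling or cols % oversampling:
        raise ValueError("canvas shape must be an integer multiple of oversampling")
    return canvas.reshape(
        rows // oversampling, oversampling, cols // oversampling, oversampling
    ).sum(axis=(1, 3))


def single_molecule_peak(psf_model, cfg: CameraConfig, mean_photons: float,
                         oversampling: int = 8) -> float:
    """Brightest pixel of an in-focus, pixel-centred average molecule.

    Used as the reference intensity against which the structured-background
    strength is defined.  Computed by rendering a mean-photon-budget kernel
    at focus, centred on a pixel, and binning.
    """
    half = 3  # pixels of support around the centre is ample at focus
    n_sub = (2 * half + 1) * oversampling
    pitch = cfg.pixel_size / oversampling
    ax = (np.arange(n_sub) - (n_sub - 1) / 2.0) * pitch
    xx, yy = np.meshgrid(ax, ax)
    vals = psf_model.evaluate(xx, yy, 0.0, None) * pitch * pitch * mean_photons
    binned = vals.reshape(2 * half + 1, oversampling, 2 * half + 1, oversampling).sum(
        axis=(1, 3)
    )
    return float(binned.max())


def build_structured_background(
    sum_image: np.ndarray,
    sfb_strength: float,
    single_molecule_peak: float,
    sfb_defocus: float,
    cfg: CameraConfig,
    psf_model=None,
) -> np.ndarray:
    """Static structured-background photon-rate map.

    The sum image of all fluorophores is convolved with the PSF at
    ``sfb_defocus`` and rescaled so its maximum equals
    ``sfb_strength x single_molecule_peak`` (background expressed as a
    fraction of the brightest pixel of a single localized molecule).
    """
    sum_image = np.asarray(sum_image, dtype=float)
    if np.any(sum_image < 0):
        raise ValueError("sum_image must be non-negative")
    if single_molecule_peak <= 0:
        raise ValueError("single_molecule_peak must be > 0")
    if sfb_strength == 0:
        return np.zeros_like(sum_image)
    if not sum_image.any():
        warnings.warn("all-zero sum image: structured background is zero")
        return np.zeros_like(sum_image)
    if psf_model is not None:
        # sample the defocused PSF kernel at pixel resolution and convolve
        pitch = cfg.pixel_size
        n = 21
        ax = (np.arange(n) - (n - 1) / 2.0) * pitch
        xx, yy = np.meshgrid(ax, ax)
        kern = psf_model.evaluate(xx, yy, sfb_defocus, None) * pitch * pitch
        kern = kern / kern.sum() if kern.sum() > 0 else kern
        blurred = ndimage.convolve(sum_image, kern, mode="constant")
    else:
        blurred = sum_image.astype(float)
    peak = blurred.max()
    if peak <= 0:
        return np.zeros_like(sum_image)
    return blurred * (sfb_strength * single_molecule_peak / peak)


def apply_camera_noise(photon_image: np.ndarray, cfg: CameraConfig, rng_seed,
                       background_rate: np.ndarray | float = 0.0) -> np.ndarray:
    """Run the EMCCD (or CCD) noise chain and return an integer ADU image."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    rate = np.asarray(photon_image, dtype=float) + background_rate
    if np.any(rate < 0):
        raise ValueError("photon rates must be non-negative")
    electrons = rng.poisson(cfg.quantum_efficiency * rate)
    if cfg.em_register:
        amplified = np.zeros_like(electrons, dtype=float)
        nz = electrons > 0
        if np.any(nz):
            amplified[nz] = rng.gamma(shape=electrons[nz], scale=cfg.em_gain)
    else:
        amplified = electrons.astype(float)
    if cfg.readout_noise_sigma > 0:
        amplified = amplified + rng.normal(0.0, cfg.readout_noise_sigma, rate.shape)
    adu = amplified * cfg.adu_per_electron + cfg.baseline
    return np.clip(np.round(adu), 0, cfg.saturation).astype(np.uint16)
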