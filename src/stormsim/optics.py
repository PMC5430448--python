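"""Point spread function models and event rendering.

Three PSF models of increasing physical fidelity are implemented:

* ``gaussian`` — the standard localization-microscopy approximation: a
  radially symmetric normal distribution whose width grows with defocus as
  ``sigma(z) = sigma0 * sqrt(1 + (z/z_R)^2)``.  Symmetric in +/-z.

* ``scalar`` — a scalar Debye pupil integral with sqrt(cos) apodization,
  defocus phase in the sample medium and a stratified-medium (immersion /
  sample index mismatch) aberration term evaluated at a nominal imaging
  depth.  At focus with matched indices it reduces to the Airy pattern; with
  mismatched indices the defocused PSF develops high-intensity side-lobe
  rings on one side of focus and is asymmetric in +/-z.

* ``dipole`` — a vector-diffraction (Richards-Wolf type) image of a fixed
  emission dipole through a high-NA aplanatic objective, optionally seen
  through a linear detection polarizer.  An axial dipole images as a
  doughnut with a central minimum; an in-plane dipole as an elliptically
  elongated spot.  Kernels are normalized so that their integral equals the
  collection efficiency relative to an in-plane dipole at focus.

Kernels are unit-integral intensity distributions h(x, y; z) sampled on a
sub-pixel grid; rendering evaluates the model directly at sub-pixel shifted
coordinates (no nearest-pixel snapping) and adds photon-weighted intensity
onto a photon-valued canvas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import j0, j1, jv

__all__ = [
    "OpticalConfig",
    "PSFKernel",
    "GaussianPSFModel",
    "ScalarPSFModel",
    "DipolePSFModel",
    "gaussian_psf",
    "scalar_psf",
    "dipole_psf",
    "render_event",
    "make_psf_model",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Detection-side optical parameters.

    ``sigma0_factor`` calibrates the in-focus Gaussian width
    ``sigma0 = sigma0_factor * wavelength / NA`` (0.21 matches the Airy core);
    ``rayleigh_range_nm`` overrides the defocus scale ``z_R`` (default
    ``n_sample * wavelength / NA^2``).  ``depth_aberration_nm`` is the nominal
    imaging depth at which the index-mismatch aberration of the scalar model
    is evaluated; with matched indices it has no effect.
    """

    NA: float = 1.4
    wavelength: float = 670.0  # emission, nm
    n_immersion: float = 1.52
    n_sample: float = 1.33
    psf_model: str = "gaussian"  # gaussian | scalar | dipole
    psf_grid_oversampling: int = 8
    psf_support_radius: float = 2000.0  # nm
    sigma0_factor: float = 0.21
    rayleigh_range_nm: float | None = None
    depth_aberration_nm: float = 1500.0
    z_bin_nm: float = 10.0
    quadrature_nodes: int = 1024

    def __post_init__(self):
        if not 0 < self.NA <= self.n_immersion:
            raise ValueError("require 0 < NA <= n_immersion")
        if self.psf_grid_oversampling < 1:
            raise ValueError("psf_grid_oversampling must be >= 1")
        if self.psf_model not in ("gaussian", "scalar", "dipole"):
            raise ValueError(f"unknown psf_model {self.psf_model!r}")

    @property
    def sigma0(self) -> float:
        return self.sigma0_factor * self.wavelength / self.NA

    @property
    def rayleigh_range(self) -> float:
        if self.rayleigh_range_nm is not None:
            return self.rayleigh_range_nm
        return self.n_sample * self.wavelength / self.NA**2

    @property
    def alpha(self) -> float:
        """Marginal-ray angle in the immersion medium."""
        return float(np.arcsin(self.NA / self.n_immersion))

    @property
    def alpha_sample(self) -> float:
        """Marginal-ray angle limited to propagating waves in the sample."""
        return float(np.arcsin(min(self.NA, self.n_sample) / self.n_immersion))


@dataclass
class PSFKernel:
    """A PSF sampled on a centred sub-pixel grid.

    ``grid[i, j]`` holds the photon fraction falling in the sub-pixel at
    ``(x, y) = ((j - c) * pitch, (i - c) * pitch)`` where ``c = (n-1)/2``.
    ``grid.sum()`` is the mass retained inside the finite support;
    ``truncation_error = 1 - mass``.
    """

    grid: np.ndarray
    pitch: float  # nm per sub-pixel

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < -1e-12):
            raise ValueError("kernel must be non-negative")

    @property
    def mass(self) -> float:
        return float(self.grid.sum())

    @property
    def truncation_error(self) -> float:
        return 1.0 - self.mass

    def coords(self):
        n = self.grid.shape[0]
        c = (n - 1) / 2.0
        ax = (np.arange(n) - c) * self.pitch
        return ax


def _kernel_axes(cfg: OpticalConfig, pixel_size: float | None = None):
    pitch = (pixel_size or 100.0) / cfg.psf_grid_oversampling
    n = int(np.ceil(cfg.psf_support_radius / pitch))
    ax = (np.arange(-n, n + 1)) * pitch
    return ax, pitch


class GaussianPSFModel:
    """Defocus-dependent symmetric Gaussian PSF."""

    def __init__(self, cfg: OpticalConfig):
        self.cfg = cfg

    def sigma(self, z: float) -> float:
        c = self.cfg
        return c.sigma0 * np.sqrt(1.0 + (z / c.rayleigh_range) ** 2)

    def evaluate(self, x, y, z: float, dipole=None):
        """Intensity per nm^2 at sample-plane offsets (x, y) for defocus z."""
        s = self.sigma(z)
        return np.exp(-(np.asarray(x) ** 2 + np.asarray(y) ** 2) / (2 * s * s)) / (
            2 * np.pi * s * s
        )


class _RadialTableMixin:
    """Cache radial profiles per defocus bin and interpolate on evaluation."""

    def _zkey(self, z: float) -> float:
        b = self.cfg.z_bin_nm
        return float(np.round(z / b) * b)


class ScalarPSFModel(_RadialTableMixin):
    """Scalar Debye-type diffraction PSF with index-mismatch aberration.

    Amplitude: U(r, z) = int_0^alpha sqrt(cos t) J0(k r n_imm sin t)
    exp(i Phi(t, z)) sin t dt, with
    Phi = k z n_s cos(t_s) + k d_ab (n_s cos t_s - n_imm cos t)
    and Snell's law n_imm sin t = n_s sin t_s.  The profile is normalized to
    unit integral over the computed radial extent at every z.
    """

    def __init__(self, cfg: OpticalConfig, r_max: float | None = None, dr: float = 4.0):
        self.cfg = cfg
        self.r_max = r_max if r_max is not None else 1.25 * cfg.psf_support_radius
        self.dr = dr
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def _amplitude(self, r: np.ndarray, z: float, n_nodes: int) -> np.ndarray:
        c = self.cfg
        k = 2 * np.pi / c.wavelength
        matched = abs(c.n_immersion - c.n_sample) < 1e-12
        alpha = c.alpha if matched else c.alpha_sample
        nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
        theta = 0.5 * alpha * (nodes + 1.0)
        w = 0.5 * alpha * weights
        st, ct = np.sin(theta), np.cos(theta)
        sts = np.clip(c.n_immersion * st / c.n_sample, 0.0, 1.0)
        cts = np.sqrt(1.0 - sts**2)
        phase = k * z * c.n_sample * cts
        if not matched:
            phase = phase + k * c.depth_aberration_nm * (
                c.n_sample * cts - c.n_immersion * ct
            )
        integrand = np.sqrt(ct) * np.exp(1j * phase) * st * w
        bess = j0(k * c.n_immersion * np.outer(r, st))
        return bess @ integrand

    def _profile(self, z: float) -> tuple[np.ndarray, np.ndarray]:
        key = self._zkey(z)
        if key not in self._cache:
            r = np.arange(0.0, self.r_max + self.dr, self.dr)
            n = self.cfg.quadrature_nodes
            u_lo = self._amplitude(r, key, n // 2)
            u = self._amplitude(r, key, n)
            i_lo, i_hi = np.abs(u_lo) ** 2, np.abs(u) ** 2
            scale = i_hi.max()
            if scale > 0 and np.max(np.abs(i_hi - i_lo)) / scale > 1e-6:
                raise RuntimeError(
                    f"pupil quadrature did not converge at z={key} nm"
                )
            intensity = i_hi
            norm = np.trapezoid(intensity * 2 * np.pi * r, r)
            self._cache[key] = (r, intensity / norm)
        return self._cache[key]

    def evaluate(self, x, y, z: float, dipole=None):
        r_grid, prof = self._profile(z)
        r = np.hypot(np.asarray(x), np.asarray(y))
        return np.interp(r, r_grid, prof, right=0.0)


class DipolePSFModel(_RadialTableMixin):
    """Vector-diffraction image of a fixed emission dipole (high NA).

    Uses the standard Richards-Wolf diffraction integrals I0, I1, I2 over
    the collection aperture; the image-plane field of a dipole
    d = (dx, dy, dz) is

        Ex ~ dx (I0 + I2 cos 2phi) + dy I2 sin 2phi - 2i dz I1 cos phi
        Ey ~ dx I2 sin 2phi + dy (I0 - I2 cos 2phi) - 2i dz I1 sin phi

    and the detected intensity is |Ex|^2 + |Ey|^2 (or the squared
    projection on a linear detection polarizer).  Supercritical-angle
    emission is excluded.  Kernels integrate to the collection efficiency
    relative to an in-plane dipole at focus.
    """

    def __init__(self, cfg: OpticalConfig, detection_polarizer=None,
                 r_max: float | None = None, dr: float = 4.0):
        self.cfg = cfg
        if detection_polarizer is not None:
            p = np.asarray(detection_polarizer, dtype=float)
            if abs(np.linalg.norm(p) - 1.0) > 1e-9:
                raise ValueError("detection_polarizer must be a unit 2-vector")
            detection_polarizer = p
        self.polarizer = detection_polarizer
        self.r_max = r_max if r_max is not None else 1.25 * cfg.psf_support_radius
        self.dr = dr
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        self._inplane_power: float | None = None

    def _integrals(self, z: float) -> tuple[np.ndarray, np.ndarray]:
        key = self._zkey(z)
        if key not in self._cache:
            c = self.cfg
            k = 2 * np.pi / c.wavelength
            matched = abs(c.n_immersion - c.n_sample) < 1e-12
            alpha = c.alpha if matched else c.alpha_sample
            n = c.quadrature_nodes
            nodes, weights = np.polynomial.legendre.leggauss(n)
            theta = 0.5 * alpha * (nodes + 1.0)
            w = 0.5 * alpha * weights
            st, ct = np.sin(theta), np.cos(theta)
            sts = np.clip(c.n_immersion * st / c.n_sample, 0.0, 1.0)
            cts = np.sqrt(1.0 - sts**2)
            phase = k * z * c.n_sample * cts
            if not matched:
                phase = phase + k * c.depth_aberration_nm * (
                    c.n_sample * cts - c.n_immersion * ct
                )
            apod = np.sqrt(ct) * np.exp(1j * phase) * st * w
            r = np.arange(0.0, self.r_max + self.dr, self.dr)
            v = k * c.n_immersion * np.outer(r, st)
            i0 = (j0(v) * (1.0 + ct)) @ apod
            i1 = (j1(v) * st) @ apod
            i2 = (jv(2, v) * (1.0 - ct)) @ apod
            self._cache[key] = (r, np.stack([i0, i1, i2]))
        return self._cache[key]

    def _field_intensity(self, x, y, z: float, dipole) -> np.ndarray:
        r_grid, (I0, I1, I2) = self._integrals(z)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.hypot(x, y)
        phi = np.arctan2(y, x)
        i0 = np.interp(r, r_grid, I0.real, right=0.0) + 1j * np.interp(
            r, r_grid, I0.imag, right=0.0
        )
        i1 = np.interp(r, r_grid, I1.real, right=0.0) + 1j * np.interp(
            r, r_grid, I1.imag, right=0.0
        )
        i2 = np.interp(r, r_grid, I2.real, right=0.0) + 1j * np.interp(
            r, r_grid, I2.imag, right=0.0
        )
        dx, dy, dz = dipole
        c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
        cp, sp = np.cos(phi), np.sin(phi)
        ex = dx * (i0 + i2 * c2) + dy * i2 * s2 - 2j * dz * i1 * cp
        ey = dx * i2 * s2 + dy * (i0 - i2 * c2) - 2j * dz * i1 * sp
        if self.polarizer is not None:
            e = self.polarizer[0] * ex + self.polarizer[1] * ey
            return np.abs(e) ** 2
        return np.abs(ex) ** 2 + np.abs(ey) ** 2

    def _total_power(self, dipole, z: float = 0.0) -> float:
        r_grid, _ = self._integrals(z)
        # integrate on a polar grid; angular dependence is low order (<= 2phi)
        phis = np.linspace(0.0, 2 * np.pi, 33)[:-1]
        rr, pp = np.meshgrid(r_grid, phis, indexing="ij")
        vals = self._field_intensity(rr * np.cos(pp), rr * np.sin(pp), z, dipole)
        ang = vals.mean(axis=1) * 2 * np.pi
        return float(np.trapezoid(ang * r_grid, r_grid))

    def _norm(self, dipole, z: float) -> float:
        key = (tuple(np.round(dipole, 6)), self._zkey(z))
        if not hasattr(self, "_norm_cache"):
            self._norm_cache: dict = {}
        if key not in self._norm_cache:
            if self._inplane_power is None:
                self._inplane_power = self._total_power((1.0, 0.0, 0.0), 0.0)
            collection = self._total_power(dipole, 0.0) / self._inplane_power
            raw = self._total_power(dipole, z)
            self._norm_cache[key] = collection / raw if raw > 0 else 0.0
        return self._norm_cache[key]

    def evaluate(self, x, y, z: float, dipole=None):
        d = np.asarray(dipole if dipole is not None else (1.0, 0.0, 0.0), float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("dipole must be a unit vector")
        return self._field_intensity(x, y, z, d) * self._norm(tuple(d), z)


def make_psf_model(cfg: OpticalConfig, detection_polarizer=None):
    """Instantiate the PSF model selected in ``cfg.psf_model``."""
    if cfg.psf_model == "gaussian":
        return GaussianPSFModel(cfg)
    if cfg.psf_model == "scalar":
        return ScalarPSFModel(cfg)
    return DipolePSFModel(cfg, detection_polarizer=detection_polarizer)


def _sample_kernel(model, cfg: OpticalConfig, z: float, dipole=None,
                   pixel_size: float = 100.0) -> PSFKernel:
    ax, pitch = _kernel_axes(cfg, pixel_size)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    vals = model.evaluate(xx, yy, z, dipole) * pitch * pitch
    return PSFKernel(grid=np.clip(vals, 0.0, None), pitch=pitch)


def gaussian_psf(z: float, cfg: OpticalConfig, pixel_size: float = 100.0) -> PSFKernel:
    """Sample the Gaussian PSF at defocus ``z`` on the sub-pixel grid."""
    return _sample_kernel(GaussianPSFModel(cfg), cfg, z, pixel_size=pixel_size)


def scalar_psf(z: float, cfg: OpticalConfig, pixel_size: float = 100.0) -> PSFKernel:
    """Sample the scalar-diffraction PSF at defocus ``z``."""
    return _sample_kernel(ScalarPSFModel(cfg), cfg, z, pixel_size=pixel_size)


def dipole_psf(dipole, z: float, cfg: OpticalConfig, detection_polarizer=None,
               pixel_size: float = 100.0) -> PSFKernel:
    """Sample the fixed-dipole vector PSF at defocus ``z``."""
    d = np.asarray(dipole, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("dipole must be a unit vector")
    model = DipolePSFModel(cfg, detection_polarizer=detection_polarizer)
    return _sample_kernel(model, cfg, z, dipole=d, pixel_size=pixel_size)


def render_event(
    canvas: np.ndarray,
    photons: float,
    position,
    model,
    cfg: OpticalConfig,
    canvas_pitch: float,
    origin=(0.0, 0.0),
    dipole=None,
) -> None:
    """Add one emission event onto the photon-valued sub-pixel canvas.

    ``canvas`` has shape (rows, cols); sub-pixel (i, j) is centred at
    ``origin + ((j + 0.5) * pitch, (i + 0.5) * pitch)`` in sample nm (x right
    along columns, y down along rows).  The kernel is evaluated at the
    exactly shifted coordinates, so sub-pixel positions are preserved.
    """
    if not np.isfinite(photons):
        raise ValueError("photon count must be finite")
    if photons <= 0:
        return
    x0 = position[0] - origin[0]
    y0 = position[1] - origin[1]
    z = position[2] if len(position) > 2 else 0.0
    if isinstance(model, GaussianPSFModel):
        support = min(cfg.psf_support_radius, 6.0 * model.sigma(z))
    else:
        support = cfg.psf_support_radius
    rows, cols = canvas.shape
    j_lo = max(int(np.floor((x0 - support) / canvas_pitch - 0.5)), 0)
    j_hi = min(int(np.ceil((x0 + support) / canvas_pitch - 0.5)) + 1, cols)
    i_lo = max(int(np.floor((y0 - support) / canvas_pitch - 0.5)), 0)
    i_hi = min(int(np.ceil((y0 + support) / canvas_pitch - 0.5)) + 1, rows)
    if j_lo >= j_hi or i_lo >= i_hi:
        return
    xs = (np.arange(j_lo, j_hi) + 0.5) * canvas_pitch - x0
    ys = (np.arange(i_lo, i_hi) + 0.5) * canvas_pitch - y0
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    vals = model.evaluate(xx, yy, z, dipole) * canvas_pitch**2
    canvas[i_lo:i_hi, j_lo:j_hi] += photons * vals
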