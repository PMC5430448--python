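"""PSF models: Gaussian defocus law, scalar diffraction, dipole imaging."""

import numpy as np
import pytest
from scipy.special import j1

from stormsim.optics import (
    OpticalConfig,
    dipole_psf,
    gaussian_psf,
    make_psf_model,
    render_event,
    scalar_psf,
)


class TestGaussianModel:
    def test_width_follows_defocus_law(self, gaussian_optics):
        model = make_psf_model(gaussian_optics)
        s0 = gaussian_optics.sigma0
        zr = gaussian_optics.rayleigh_range
        for z in (0.0, 200.0, -200.0, 800.0):
            expected = s0 * np.sqrt(1 + (z / zr) ** 2)
            assert model.sigma(z) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_in_defocus_sign(self, gaussian_optics):
        model = make_psf_model(gaussian_optics)
        r = np.linspace(0, 800, 50)
        up = model.evaluate(r, np.zeros_like(r), 400.0, None)
        dn = model.evaluate(r, np.zeros_like(r), -400.0, None)
        assert np.allclose(up, dn, rtol=1e-12)

    def test_kernel_mass_is_unity(self, gaussian_optics):
        k = gaussian_psf(0.0, gaussian_optics)
        assert k.mass == pytest.approx(1.0, abs=1e-3)

    def test_default_width_is_airy_matched(self, gaussian_optics):
        assert gaussian_optics.sigma0 == pytest.approx(
            0.21 * gaussian_optics.wavelength / gaussian_optics.NA
        )


class TestScalarModel:
    def test_reduces_to_airy_in_paraxial_matched_limit(self):
        NA, lam = 0.05, 670.0
        airy_r = 0.61 * lam / NA
        cfg = OpticalConfig(
            NA=NA, wavelength=lam, n_immersion=1.0, n_sample=1.0,
            psf_model="scalar", depth_aberration_nm=0.0,
            psf_support_radius=3.2 * airy_r,
        )
        model = make_psf_model(cfg)
        r = np.linspace(0.0, 3 * airy_r, 400)
        vals = model.evaluate(r, np.zeros_like(r), 0.0, None)
        vals = vals / vals.max()
        v = np.where(r > 0, 2 * np.pi / lam * NA * r, 1e-12)
        airy = (2 * j1(v) / v) ** 2
        airy[0] = 1.0
        assert np.max(np.abs(vals - airy)) < 1e-3

    def test_first_zero_at_061_lambda_over_na(self):
        NA, lam = 0.05, 670.0
        airy_r = 0.61 * lam / NA
        cfg = OpticalConfig(
            NA=NA, wavelength=lam, n_immersion=1.0, n_sample=1.0,
            psf_model="scalar", depth_aberration_nm=0.0,
            psf_support_radius=3.2 * airy_r,
        )
        model = make_psf_model(cfg)
        rr = np.linspace(0.8 * airy_r, 1.2 * airy_r, 600)
        prof = model.evaluate(rr, np.zeros_like(rr), 0.0, None)
        r0 = rr[np.argmin(prof)]
        assert abs(r0 - airy_r) / airy_r < 0.01

    def test_profile_monotone_decreasing_to_first_zero(self):
        cfg = OpticalConfig(
            NA=0.05, wavelength=670.0, n_immersion=1.0, n_sample=1.0,
            psf_model="scalar", depth_aberration_nm=0.0,
            psf_support_radius=3.2 * 0.61 * 670.0 / 0.05,
        )
        model = make_psf_model(cfg)
        r = np.linspace(0.0, 0.61 * 670.0 / 0.05, 200)
        prof = model.evaluate(r, np.zeros_like(r), 0.0, None)
        assert np.all(np.diff(prof) < 0)

    def test_matched_indices_symmetric_in_defocus(self, matched_scalar_optics):
        model = make_psf_model(matched_scalar_optics)
        r = np.linspace(0, 1500, 120)
        up = model.evaluate(r, np.zeros_like(r), 400.0, None)
        dn = model.evaluate(r, np.zeros_like(r), -400.0, None)
        assert np.max(np.abs(up - dn)) / up.max() < 1e-6

    def test_index_mismatch_breaks_defocus_symmetry(self, scalar_optics):
        model = make_psf_model(scalar_optics)
        r = np.linspace(0, 2000, 200)
        z0 = np.zeros_like(r)
        up = model.evaluate(r, z0, 600.0, None)
        dn = model.evaluate(r, z0, -600.0, None)
        peak = model.evaluate(r, z0, 0.0, None).max()
        assert np.max(np.abs(up - dn)) / peak > 0.05

    def test_defocused_profile_develops_ring_structure(self, scalar_optics):
        model = make_psf_model(scalar_optics)
        r = np.linspace(0, 1500, 400)
        prof = model.evaluate(r, np.zeros_like(r), -600.0, None)
        # local minima followed by local maxima: side lobes
        interior = prof[1:-1]
        minima = (interior < prof[:-2]) & (interior < prof[2:])
        maxima = (interior > prof[:-2]) & (interior > prof[2:])
        assert minima.any() and maxima.any()

    def test_kernel_mass_in_energy_window(self, scalar_optics):
        for z in (0.0, 400.0, -400.0):
            k = scalar_psf(z, scalar_optics)
            assert 0.9 <= k.mass <= 1.0


class TestDipoleModel:
    CFG = OpticalConfig(psf_model="dipole")

    def test_axial_dipole_doughnut_has_central_minimum(self):
        model = make_psf_model(self.CFG)
        g = np.linspace(-500, 500, 41)
        X, Y = np.meshgrid(g, g)
        img = model.evaluate(X.ravel(), Y.ravel(), 0.0,
                             np.array([0.0, 0.0, 1.0])).reshape(X.shape)
        centre = img[20, 20]
        assert centre < 0.05 * img.max()

    def test_inplane_dipole_elliptical(self):
        model = make_psf_model(self.CFG)
        g = np.linspace(-600, 600, 61)
        X, Y = np.meshgrid(g, g)
        img = model.evaluate(X.ravel(), Y.ravel(), 0.0,
                             np.array([1.0, 0.0, 0.0])).reshape(X.shape)
        w = img / img.sum()
        ratio = (w * Y**2).sum() / (w * X**2).sum()
        assert ratio > 1.02

    def test_x_and_y_dipoles_related_by_rotation(self):
        model = make_psf_model(self.CFG)
        g = np.linspace(-600, 600, 41)
        X, Y = np.meshgrid(g, g)
        ix = model.evaluate(X.ravel(), Y.ravel(), 0.0,
                            np.array([1.0, 0.0, 0.0])).reshape(X.shape)
        iy = model.evaluate(X.ravel(), Y.ravel(), 0.0,
                            np.array([0.0, 1.0, 0.0])).reshape(X.shape)
        assert np.max(np.abs(ix - iy.T)) / ix.max() < 1e-9

    def test_axial_dipole_collected_less_efficiently(self):
        kz = dipole_psf(np.array([0.0, 0.0, 1.0]), 0.0, self.CFG)
        kx = dipole_psf(np.array([1.0, 0.0, 0.0]), 0.0, self.CFG)
        assert kz.mass < 0.75 * kx.mass
        assert 0.9 <= kx.mass <= 1.0

    def test_isotropic_average_radially_symmetric(self):
        model = make_psf_model(self.CFG)
        g = np.linspace(-500, 500, 41)
        X, Y = np.meshgrid(g, g)
        # Fibonacci sphere quadrature over dipole orientations
        n = 64
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        dirs = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
             np.cos(phi)], axis=1,
        )
        acc = np.zeros_like(X)
        for d in dirs:
            acc += model.evaluate(X.ravel(), Y.ravel(), 0.0, d).reshape(X.shape)
        cx = acc[20, :]
        cy = acc[:, 20]
        assert np.max(np.abs(cx - cy)) / acc.max() < 0.01

    def test_rejects_non_unit_dipole(self):
        model = make_psf_model(self.CFG)
        with pytest.raises(ValueError):
            model.evaluate(np.zeros(1), np.zeros(1), 0.0,
                           np.array([2.0, 0.0, 0.0]))


class TestRenderEvent:
    def test_in_focus_event_deposits_budget_within_truncation(self,
                                                              gaussian_optics):
        model = make_psf_model(gaussian_optics)
        canvas = np.zeros((256, 256))
        render_event(canvas, 1000.0, (1600.0, 1600.0, 0.0), model,
                     gaussian_optics, 12.5)
        assert 900.0 <= canvas.sum() <= 1000.0

    def test_event_far_outside_fov_leaves_canvas_unchanged(self,
                                                           gaussian_optics):
        model = make_psf_model(gaussian_optics)
        canvas = np.zeros((64, 64))
        render_event(canvas, 1000.0, (1e6, 1e6, 0.0), model,
                     gaussian_optics, 12.5)
        assert canvas.sum() == 0.0

    def test_linearity_of_superposition(self, gaussian_optics):
        model = make_psf_model(gaussian_optics)
        a = np.zeros((128, 128))
        b = np.zeros((128, 128))
        pos = (800.0, 775.0, 100.0)
        render_event(a, 500.0, pos, model, gaussian_optics, 12.5)
        render_event(a, 500.0, pos, model, gaussian_optics, 12.5)
        render_event(b, 1000.0, pos, model, gaussian_optics, 12.5)
        assert np.allclose(a, b, atol=1e-9)

    def test_subpixel_shift_moves_centroid(self, gaussian_optics):
        model = make_psf_model(gaussian_optics)
        pitch = 12.5
        a = np.zeros((128, 128))
        b = np.zeros((128, 128))
        render_event(a, 1000.0, (800.0, 800.0, 0.0), model,
                     gaussian_optics, pitch)
        render_event(b, 1000.0, (806.0, 800.0, 0.0), model,
                     gaussian_optics, pitch)
        x = (np.arange(128) + 0.5) * pitch
        ca = (a.sum(axis=0) * x).sum() / a.sum()
        cb = (b.sum(axis=0) * x).sum() / b.sum()
        assert cb - ca == pytest.approx(6.0, abs=0.05)

    def test_nan_photons_rejected(self, gaussian_optics):
        model = make_psf_model(gaussian_optics)
        with pytest.raises(ValueError):
            render_event(np.zeros((8, 8)), float("nan"), (0.0, 0.0, 0.0),
                         model, gaussian_optics, 12.5)


class TestQuadratureAccuracy:
    def test_insufficient_nodes_raise_rather_than_return_garbage(self):
        cfg = OpticalConfig(psf_model="scalar", quadrature_nodes=32)
        model = make_psf_model(cfg)
        with pytest.raises(RuntimeError):
            model.evaluate(np.zeros(1), np.zeros(1), 900.0, None)
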