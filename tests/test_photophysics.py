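"""Blinking kinetics, photoselection, and photon budgets."""

import numpy as np
import pytest

from stormsim.patterns import (
    AxonSegmentSpec,
    LabelingSpec,
    generate_axon_pattern,
    place_labels,
)
from stormsim.photophysics import (
    DyeModel,
    ExcitationSpec,
    draw_photon_counts,
    photoselection_weight,
    simulate_switching,
)


def _labeled(density=60.0, dipole_mode="free_rotating", seed=0, **spec_kw):
    eps = generate_axon_pattern([AxonSegmentSpec()], density, rng_seed=seed)
    return place_labels(
        eps, LabelingSpec(dipole_mode=dipole_mode, **spec_kw), rng_seed=seed + 1
    )


class TestPhotoselection:
    def test_linear_polarization_cos_squared_exact(self):
        exc = ExcitationSpec(
            laser_wavelength=647.0, polarization="linear",
            linear_direction=(1.0, 0.0),
        )
        for theta in np.linspace(0, np.pi, 13):
            d = np.array([np.cos(theta), np.sin(theta), 0.0])
            assert photoselection_weight(d, exc) == pytest.approx(
                np.cos(theta) ** 2, abs=1e-12
            )

    def test_longitudinal_field_selects_axial_component(self):
        exc = ExcitationSpec(laser_wavelength=647.0, polarization="longitudinal_z")
        d = np.array([0.6, 0.0, 0.8])
        assert photoselection_weight(d, exc) == pytest.approx(0.64, abs=1e-12)

    def test_circular_averages_in_plane_components(self):
        exc = ExcitationSpec(laser_wavelength=647.0, polarization="circular_xy")
        d = np.array([0.6, 0.0, 0.8])
        assert photoselection_weight(d, exc) == pytest.approx(0.18, abs=1e-12)

    def test_perpendicular_dipole_is_never_excited(self):
        exc = ExcitationSpec(
            laser_wavelength=647.0, polarization="linear",
            linear_direction=(1.0, 0.0),
        )
        assert photoselection_weight(np.array([0.0, 1.0, 0.0]), exc) == 0.0

    def test_sphere_average_of_cos_squared_is_one_third(self):
        exc = ExcitationSpec(
            laser_wavelength=647.0, polarization="linear",
            linear_direction=(1.0, 0.0),
        )
        rng = np.random.default_rng(0)
        d = rng.standard_normal((200_000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        w = np.mean([photoselection_weight(di, exc) for di in d[:5000]])
        assert w == pytest.approx(1.0 / 3.0, abs=0.02)


class TestPhotonBudget:
    def test_exponential_budget_mean(self):
        rng = np.random.default_rng(0)
        draws = np.array([draw_photon_counts(4000.0, rng) for _ in range(20000)])
        assert draws.mean() == pytest.approx(4000.0, rel=0.03)

    def test_budget_is_nonnegative_integerlike(self):
        rng = np.random.default_rng(1)
        draws = np.array([draw_photon_counts(50.0, rng) for _ in range(1000)])
        assert np.all(draws >= 0)
        assert np.allclose(draws, np.round(draws))


class TestSwitching:
    EXC = ExcitationSpec(laser_wavelength=647.0)

    def test_immediate_bleaching_gives_at_most_one_event_each(self):
        dye = DyeModel(
            name="d", on_rate=0.5, off_rate=1.0, bleach_probability_per_cycle=1.0
        )
        labeled = _labeled()
        events = simulate_switching(labeled, dye, self.EXC, n_frames=200, rng_seed=3)
        per_mol = np.bincount(
            [e.fluorophore_id for e in events], minlength=len(labeled)
        )
        assert np.all(per_mol <= 1)

    def test_mean_switching_cycles_inverse_of_bleach_probability(self):
        # run long enough that every fluorophore bleaches
        dye = DyeModel(
            name="d", on_rate=0.2, off_rate=1.0, bleach_probability_per_cycle=0.05
        )
        labeled = _labeled(density=200.0)
        events = simulate_switching(
            labeled, dye, self.EXC, n_frames=5000, rng_seed=4
        )
        per_mol = np.bincount(
            [e.fluorophore_id for e in events], minlength=len(labeled)
        )
        mean = per_mol.mean()
        se = per_mol.std(ddof=1) / np.sqrt(len(per_mol))
        assert abs(mean - 20.0) < 3 * se

    def test_event_photons_split_proportionally_across_frames(self):
        dye = DyeModel(name="d", on_rate=0.05, off_rate=0.3)
        labeled = _labeled()
        events = simulate_switching(labeled, dye, self.EXC, n_frames=100, rng_seed=5)
        assert events, "expected some events"
        for e in events:
            assert e.frame_end >= e.frame_start
            assert len(e.photons_per_frame) == e.frame_end - e.frame_start + 1
            assert np.isclose(np.sum(e.photons_per_frame), e.photons_total)
            assert np.all(np.asarray(e.photons_per_frame) >= 0)

    def test_events_respect_acquisition_bounds(self):
        dye = DyeModel(name="d", on_rate=0.1, off_rate=0.2)
        events = simulate_switching(
            _labeled(), dye, self.EXC, n_frames=50, rng_seed=6
        )
        for e in events:
            assert 0 <= e.frame_start <= e.frame_end < 50

    def test_excitation_efficiency_scales_event_rate_and_brightness(self):
        dye = DyeModel(name="d", on_rate=0.05, off_rate=1.0,
                       bleach_probability_per_cycle=0.0)
        labeled = _labeled(density=150.0)
        full = simulate_switching(
            labeled, dye, self.EXC, n_frames=400, rng_seed=7,
            excitation_efficiency=1.0,
        )
        weak = simulate_switching(
            labeled, dye, self.EXC, n_frames=400, rng_seed=7,
            excitation_efficiency=0.075,
        )
        assert 0.04 < len(weak) / len(full) < 0.13
        mean_full = np.mean([e.photons_total for e in full])
        mean_weak = np.mean([e.photons_total for e in weak])
        assert 0.04 < mean_weak / mean_full < 0.13

    def test_fixed_dipole_total_photons_scale_with_weight(self):
        # with full bleaching the total cycle count is rate-independent, so
        # total emitted photons scale linearly with the cos^2 weight
        exc = ExcitationSpec(
            laser_wavelength=647.0, polarization="linear",
            linear_direction=(1.0, 0.0),
        )
        eps = generate_axon_pattern(
            [AxonSegmentSpec(axis_direction=(0.0, 0.0, 1.0))], 400.0, rng_seed=8
        )
        labeled = place_labels(
            eps, LabelingSpec(dipole_mode="fixed_custom",
                              custom_dipole=(1.0, 0.0, 0.0)),
            rng_seed=9,
        )
        half = place_labels(
            eps,
            LabelingSpec(
                dipole_mode="fixed_custom",
                custom_dipole=(np.sqrt(0.5), np.sqrt(0.5), 0.0),
            ),
            rng_seed=9,
        )
        dye = DyeModel(name="d", on_rate=0.05, off_rate=1.0,
                       bleach_probability_per_cycle=0.1)
        tot_full = sum(
            e.photons_total
            for e in simulate_switching(labeled, dye, exc, 4000, rng_seed=10)
        )
        tot_half = sum(
            e.photons_total
            for e in simulate_switching(half, dye, exc, 4000, rng_seed=10)
        )
        assert tot_half / tot_full == pytest.approx(0.5, rel=0.15)

    def test_flexible_linker_resamples_position_each_event(self):
        dye = DyeModel(name="d", on_rate=0.1, off_rate=1.0,
                       bleach_probability_per_cycle=0.0)
        labeled = _labeled(linker_mode="flexible", linker_length=15.0)
        events = simulate_switching(labeled, dye, self.EXC, 300, rng_seed=11)
        by_mol: dict[int, list] = {}
        for e in events:
            by_mol.setdefault(e.fluorophore_id, []).append(e.position)
        multi = [v for v in by_mol.values() if len(v) >= 2]
        assert multi, "expected repeat events"
        moved = [np.linalg.norm(v[0] - v[1]) > 1e-9 for v in multi]
        assert all(moved)
        # and every event sits exactly one linker length from its epitope
        for e in events:
            d = np.linalg.norm(
                e.position - labeled.epitope_positions[e.fluorophore_id]
            )
            assert d == pytest.approx(15.0, abs=1e-9)

    def test_requires_at_least_one_frame(self):
        dye = DyeModel(name="d")
        with pytest.raises(ValueError):
            simulate_switching(_labeled(), dye, self.EXC, n_frames=0, rng_seed=0)
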