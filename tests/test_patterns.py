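"""Ground-truth geometry: rings, lines, vesicles, and linker attachment."""

import numpy as np
import pytest

from stormsim.patterns import (
    AxonSegmentSpec,
    EpitopeSet,
    LabelingSpec,
    LinePatternSpec,
    VesicleSpec,
    generate_axon_pattern,
    generate_line_pattern,
    generate_vesicle_pattern,
    place_labels,
)


class TestAxonPattern:
    def test_expected_count_matches_density_times_circumference(self):
        # one ring, R = 300 nm, 50 labels/um -> Poisson mean 50 * 2pi*0.3
        seg = AxonSegmentSpec(n_rings=1, ring_radius=300.0)
        mean_expected = 50.0 * 2.0 * np.pi * 0.3
        counts = [
            len(generate_axon_pattern([seg], 50.0, rng_seed=s)) for s in range(400)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - mean_expected) < 3 * se + 1e-9

    def test_zero_density_gives_empty_set(self):
        seg = AxonSegmentSpec()
        assert len(generate_axon_pattern([seg], 0.0, rng_seed=0)) == 0

    def test_epitopes_lie_exactly_on_circles(self):
        seg = AxonSegmentSpec(
            center=(100.0, 200.0, 50.0), axis_direction=(0.0, 1.0, 0.0)
        )
        eps = generate_axon_pattern([seg], 80.0, rng_seed=3)
        rel = eps.positions - np.asarray(seg.center)
        axial = rel @ np.array([0.0, 1.0, 0.0])
        radial = np.linalg.norm(rel - np.outer(axial, [0.0, 1.0, 0.0]), axis=1)
        assert np.allclose(radial, seg.ring_radius, atol=1e-9)
        # axial positions coincide with one of the ring planes
        planes = (np.arange(seg.n_rings) - (seg.n_rings - 1) / 2) * seg.ring_spacing
        dist_to_plane = np.min(np.abs(axial[:, None] - planes[None, :]), axis=1)
        assert np.allclose(dist_to_plane, 0.0, atol=1e-9)

    def test_out_of_focus_segment_keeps_z_within_ring_radius(self):
        seg = AxonSegmentSpec(center=(0.0, 0.0, -800.0))
        eps = generate_axon_pattern([seg], 100.0, rng_seed=1)
        assert np.all(np.abs(eps.positions[:, 2] - (-800.0)) <= seg.ring_radius + 1e-9)

    def test_triads_are_radial_tangential_axial(self):
        seg = AxonSegmentSpec()
        eps = generate_axon_pattern([seg], 60.0, rng_seed=5)
        # radial vector points from the ring centre to the epitope
        rel = eps.positions - np.array(seg.center)
        axis = np.array(seg.axis_direction)
        axial_comp = rel @ axis
        radial_vec = rel - np.outer(axial_comp, axis)
        radial_vec /= np.linalg.norm(radial_vec, axis=1, keepdims=True)
        assert np.allclose(eps.triads[:, 0, :], radial_vec, atol=1e-9)
        assert np.allclose(eps.triads[:, 2, :], axis, atol=1e-9)

    def test_rejects_non_unit_axis(self):
        with pytest.raises(ValueError):
            AxonSegmentSpec(axis_direction=(1.0, 1.0, 0.0))

    def test_rejects_negative_density(self):
        with pytest.raises(ValueError):
            generate_axon_pattern([AxonSegmentSpec()], -1.0, rng_seed=0)


class TestLinePattern:
    def test_poisson_count_on_straight_line(self):
        # 10 um line at 50/um -> mean 500
        spec = LinePatternSpec(polylines=(((0.0, 0.0), (10000.0, 0.0)),))
        counts = [
            len(generate_line_pattern(spec, 50.0, rng_seed=s)) for s in range(200)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 500.0) < 3 * se + 1e-9

    def test_epitopes_exactly_on_the_line(self):
        spec = LinePatternSpec(polylines=(((0.0, 0.0), (5000.0, 0.0)),))
        eps = generate_line_pattern(spec, 20.0, rng_seed=2)
        assert np.allclose(eps.positions[:, 1], 0.0, atol=1e-9)
        assert np.all(eps.positions[:, 0] >= -1e-9)
        assert np.all(eps.positions[:, 0] <= 5000.0 + 1e-9)

    def test_two_parallel_lines_keep_transverse_gap(self):
        spec = LinePatternSpec(
            polylines=(
                ((0.0, 0.0), (3000.0, 0.0)),
                ((0.0, 100.0), (3000.0, 100.0)),
            )
        )
        eps = generate_line_pattern(spec, 30.0, rng_seed=4)
        y = eps.positions[:, 1]
        assert set(np.round(y, 6)).issubset({0.0, 100.0})

    def test_zero_density_gives_empty_set(self):
        spec = LinePatternSpec(polylines=(((0.0, 0.0), (1000.0, 0.0)),))
        assert len(generate_line_pattern(spec, 0.0, rng_seed=0)) == 0

    def test_rejects_empty_polyline_list(self):
        with pytest.raises(ValueError):
            LinePatternSpec(polylines=())


class TestVesiclePattern:
    def test_points_on_sphere_surface(self):
        spec = VesicleSpec(
            centers=((0.0, 0.0, 0.0),), radius=200.0, surface_density=100.0
        )
        eps = generate_vesicle_pattern(spec, rng_seed=0)
        r = np.linalg.norm(eps.positions, axis=1)
        assert np.allclose(r, 200.0, atol=1e-9)

    def test_empirical_mean_count(self):
        # density chosen so the expected count is 40
        radius = 200.0
        area_um2 = 4.0 * np.pi * (radius / 1000.0) ** 2
        spec = VesicleSpec(
            centers=((0.0, 0.0, 0.0),),
            radius=radius,
            surface_density=40.0 / area_um2,
        )
        counts = [
            len(generate_vesicle_pattern(spec, rng_seed=s)) for s in range(1000)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 40.0) < 3 * se + 1e-9

    def test_uniformity_on_sphere(self):
        # z-coordinate of uniform points on a sphere is uniform on [-R, R]
        spec = VesicleSpec(
            centers=((0.0, 0.0, 0.0),), radius=100.0, surface_density=5000.0
        )
        eps = generate_vesicle_pattern(spec, rng_seed=7)
        z = eps.positions[:, 2] / 100.0
        hist, _ = np.histogram(z, bins=10, range=(-1, 1))
        expected = len(z) / 10.0
        chi2 = np.sum((hist - expected) ** 2 / expected)
        assert chi2 < 27.9  # chi-square 9 dof, p = 0.001

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            VesicleSpec(centers=((0.0, 0.0, 0.0),), radius=0.0, surface_density=1.0)


class TestEpitopeSet:
    def test_rejects_non_orthonormal_triads(self):
        bad = np.eye(3)[None] * 2.0
        with pytest.raises(ValueError):
            EpitopeSet(np.zeros((1, 3)), bad, np.zeros(1, dtype=int))

    def test_concatenate_preserves_order_and_length(self):
        a = generate_axon_pattern([AxonSegmentSpec()], 30.0, rng_seed=0)
        b = generate_axon_pattern([AxonSegmentSpec()], 30.0, rng_seed=1)
        c = EpitopeSet.concatenate([a, b])
        assert len(c) == len(a) + len(b)
        assert np.allclose(c.positions[: len(a)], a.positions)


class TestPlaceLabels:
    def test_rigid_linker_displaces_by_exact_length(self):
        eps = generate_axon_pattern([AxonSegmentSpec()], 60.0, rng_seed=0)
        spec = LabelingSpec(linker_length=12.0, linker_mode="rigid")
        labeled = place_labels(eps, spec, rng_seed=1)
        d = np.linalg.norm(labeled.positions - eps.positions, axis=1)
        assert np.allclose(d, 12.0, atol=1e-9)

    def test_zero_linker_keeps_positions(self):
        eps = generate_axon_pattern([AxonSegmentSpec()], 60.0, rng_seed=0)
        labeled = place_labels(eps, LabelingSpec(linker_length=0.0), rng_seed=1)
        assert np.allclose(labeled.positions, eps.positions)

    def test_fixed_radial_dipoles_follow_triad(self):
        eps = generate_axon_pattern([AxonSegmentSpec()], 60.0, rng_seed=0)
        labeled = place_labels(
            eps, LabelingSpec(dipole_mode="fixed_radial"), rng_seed=1
        )
        assert np.allclose(labeled.dipoles, eps.triads[:, 0, :], atol=1e-12)

    def test_fixed_custom_dipole(self):
        eps = generate_axon_pattern([AxonSegmentSpec()], 40.0, rng_seed=0)
        spec = LabelingSpec(dipole_mode="fixed_custom", custom_dipole=(0.0, 0.0, 1.0))
        labeled = place_labels(eps, spec, rng_seed=1)
        assert np.allclose(labeled.dipoles, [0.0, 0.0, 1.0])

    def test_dipoles_are_unit_vectors(self):
        eps = generate_axon_pattern([AxonSegmentSpec()], 60.0, rng_seed=0)
        for mode in ("free_rotating", "fixed_radial", "fixed_azimuthal"):
            labeled = place_labels(eps, LabelingSpec(dipole_mode=mode), rng_seed=2)
            norms = np.linalg.norm(labeled.dipoles, axis=1)
            assert np.allclose(norms, 1.0, atol=1e-9)
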