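"""MVEE fitting, ellipsoidal coordinates and equal-volume shell partitioning."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aeromorph.ellipsoid import (
    EllipsoidModel,
    assign_regions,
    fit_bounding_ellipsoid,
    mvee,
    region_mass_fractions,
    shell_boundaries,
)

from conftest import uniform_ball, water_frame


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


class TestMVEE:
    def test_sphere_point_set(self):
        pts = fibonacci_sphere(400) * 150.0 + np.array([10.0, -5.0, 3.0])
        model = mvee(pts, tolerance=1e-4)
        np.testing.assert_allclose(model.semi_axes, 150.0, rtol=2e-3)
        np.testing.assert_allclose(model.center, [10.0, -5.0, 3.0], atol=0.5)

    def test_axis_aligned_ellipsoid(self):
        axes = np.array([200.0, 150.0, 100.0])
        pts = fibonacci_sphere(600) * axes
        model = mvee(pts, tolerance=1e-4)
        np.testing.assert_allclose(model.semi_axes, axes, rtol=2e-3)
        # recovered principal directions match the coordinate axes
        overlap = np.abs(model.rotation)
        np.testing.assert_allclose(overlap.max(axis=0), 1.0, atol=1e-2)

    def test_rotated_ellipsoid_recovers_axes(self):
        axes = np.array([200.0, 150.0, 100.0])
        R = Rotation.from_euler("zyx", [30, 45, 10], degrees=True).as_matrix()
        pts = (fibonacci_sphere(600) * axes) @ R.T
        model = mvee(pts, tolerance=1e-4)
        np.testing.assert_allclose(model.semi_axes, axes, rtol=2e-3)

    def test_all_points_enclosed(self, rng):
        pts = rng.normal(size=(300, 3)) * np.array([5.0, 2.0, 1.0])
        model = mvee(pts, tolerance=1e-3)
        assert np.all(model.u(pts) <= 1.0 + 5e-3)

    def test_tetrahedron_circumsphere(self):
        # the MVEE of a regular tetrahedron is its circumscribed sphere
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        model = mvee(pts, tolerance=1e-6)
        np.testing.assert_allclose(model.semi_axes, np.sqrt(3.0), rtol=1e-3)
        np.testing.assert_allclose(model.center, 0.0, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mvee(np.zeros((3, 3)))


class TestFitBoundingEllipsoid:
    def test_matches_direct_mvee_on_frame(self):
        pts = fibonacci_sphere(500) * 120.0
        model = fit_bounding_ellipsoid(water_frame(pts))
        np.testing.assert_allclose(model.semi_axes, 120.0, rtol=5e-3)

    def test_degenerate_coplanar_raises(self):
        pts = np.zeros((50, 3))
        pts[:, :2] = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_bounding_ellipsoid(water_frame(pts))

    def test_exclude_vapor_ignores_strays(self, rng):
        pts = uniform_ball(rng, 800, 100.0)
        stray = np.array([[400.0, 0.0, 0.0], [0.0, -380.0, 0.0]])
        frame = water_frame(np.concatenate([pts, stray]))
        fitted = fit_bounding_ellipsoid(frame, exclude_vapor=True)
        assert fitted.semi_axes[0] < 130.0
        inflated = fit_bounding_ellipsoid(frame, exclude_vapor=False)
        assert inflated.semi_axes[0] > 300.0


class TestEllipsoidModel:
    def test_u_coordinate_closed_form(self):
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.array([4.0, 2.0, 1.0]), rotation=np.eye(3)
        )
        np.testing.assert_allclose(model.u([[4, 0, 0], [0, 2, 0], [0, 0, 0.5]]), [1, 1, 0.5])

    def test_rotation_idempotence(self):
        # rotating points and rotation together leaves u unchanged
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.array([5.0, 3.0, 2.0]), rotation=np.eye(3)
        )
        rotated = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.array([5.0, 3.0, 2.0]), rotation=R
        )
        pts = np.random.default_rng(1).normal(size=(40, 3)) * 3
        np.testing.assert_allclose(model.u(pts), rotated.u(pts @ R.T), atol=1e-6)

    def test_volume_and_area_sphere(self):
        R = 10.0
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.full(3, R), rotation=np.eye(3)
        )
        assert model.volume == pytest.approx(4 / 3 * np.pi * R**3, rel=1e-12)
        assert model.surface_area() == pytest.approx(4 * np.pi * R**2, rel=1e-12)

    def test_outward_normal_on_sphere_is_radial(self):
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.full(3, 7.0), rotation=np.eye(3)
        )
        pts = fibonacci_sphere(20) * 7.0
        np.testing.assert_allclose(model.outward_normal(pts), pts / 7.0, atol=1e-12)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            EllipsoidModel(
                center=np.zeros(3), semi_axes=np.array([1.0, 2.0, 3.0]), rotation=np.eye(3)
            )


class TestShellPartitioning:
    def test_boundaries_closed_form(self):
        np.testing.assert_allclose(
            shell_boundaries(3), [(1 / 3) ** (1 / 3), (2 / 3) ** (1 / 3), 1.0], atol=1e-15
        )
        np.testing.assert_allclose(shell_boundaries(1), [1.0])

    def test_invalid_shell_count(self):
        with pytest.raises(ValueError):
            shell_boundaries(0)

    def test_uniform_ball_splits_in_thirds(self, rng):
        # Monte-Carlo oracle: a uniform-density ellipsoid puts 1/3 of its
        # mass in each equal-volume region
        n = 100_000
        pts = uniform_ball(rng, n, 1.0) * np.array([120.0, 90.0, 60.0])
        frame = water_frame(pts)
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.array([120.0, 90.0, 60.0]), rotation=np.eye(3)
        )
        labels = assign_regions(frame, model)
        fractions = np.bincount(labels, minlength=3) / n
        np.testing.assert_allclose(fractions, 1 / 3, atol=0.01)

    def test_points_outside_go_to_surface_region(self):
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.full(3, 10.0), rotation=np.eye(3)
        )
        frame = water_frame(np.array([[0.0, 0.0, 25.0]]))
        assert assign_regions(frame, model)[0] == 2

    def test_region_fractions_trivial_cases(self):
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.full(3, 10.0), rotation=np.eye(3)
        )
        # all beads at the centre -> 100% core for that class
        frame = water_frame(np.full((20, 3), 0.1))
        labels = assign_regions(frame, model)
        part = region_mass_fractions(frame, labels)
        np.testing.assert_allclose(part.row("water"), [100.0, 0.0, 0.0])
        assert part.region_names == ("core", "bulk", "surface")

    def test_region_fractions_rows_sum_to_100(self, rng):
        pts = uniform_ball(rng, 500, 10.0)
        frame = water_frame(pts)
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.full(3, 10.0), rotation=np.eye(3)
        )
        part = region_mass_fractions(frame, assign_regions(frame, model))
        np.testing.assert_allclose(part.table.sum(axis=1), 100.0, rtol=1e-12)
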