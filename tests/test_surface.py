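"""Surface coverage, excess, curvature and atmospheric exposure."""

import numpy as np
import pytest

from aeromorph.clustering import cluster_lipids, identify_surface_rafts, lipid_features
from aeromorph.ellipsoid import EllipsoidModel, fit_bounding_ellipsoid
from aeromorph.generate import generate_raft_fixture
from aeromorph.surface import (
    build_surface_report,
    residue_exposure,
    surface_coverage,
    surface_excess,
    surface_sites,
)

from conftest import lipid_frame, static_trajectory


def sphere_model(R: float) -> EllipsoidModel:
    return EllipsoidModel(center=np.zeros(3), semi_axes=np.full(3, R), rotation=np.eye(3))


class TestSitesCoverageExcess:
    def test_sites_sphere_closed_form(self):
        R, a_lipid = 100.0, 21.0
        assert surface_sites(sphere_model(R), a_lipid) == pytest.approx(
            4 * np.pi * R**2 / a_lipid, rel=1e-12
        )

    def test_coverage_zero_and_full(self):
        model = sphere_model(50.0)
        assert surface_coverage(0, model) == 0.0
        n_full = int(round(surface_sites(model)))
        # placing exactly as many lipids as sites covers ~100%
        assert surface_coverage(n_full, model) == pytest.approx(100.0, abs=0.1)

    def test_excess_unity_when_counts_match_sites(self):
        # choose a_lipid = A / 1000 so the surface has exactly 1000 sites
        model = sphere_model(80.0)
        a_lipid = model.surface_area() / 1000.0
        predicted, measured = surface_excess(1000, 1000, model, a_lipid)
        assert predicted == pytest.approx(1.0, rel=1e-12)
        assert measured == pytest.approx(1.0, rel=1e-12)

    def test_excess_deficit_and_surplus(self):
        model = sphere_model(80.0)
        a_lipid = model.surface_area() / 1000.0
        predicted, measured = surface_excess(2000, 500, model, a_lipid)
        assert predicted == pytest.approx(2.0, rel=1e-12)
        assert measured == pytest.approx(0.5, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            surface_excess(-1, 0, sphere_model(10.0))

    def test_bad_a_lipid_rejected(self):
        with pytest.raises(ValueError):
            surface_sites(sphere_model(10.0), 0.0)


class TestCurvature:
    def test_sphere_is_one_over_R(self):
        R = 150.0
        model = sphere_model(R)
        pts = np.random.default_rng(0).normal(size=(50, 3))
        np.testing.assert_allclose(model.mean_curvature(pts), 1.0 / R, rtol=1e-12)

    def test_triaxial_axis_points_closed_form(self):
        # principal-curvature oracle at axis intersections: at (a,0,0) the
        # principal curvatures are a/b^2 and a/c^2, so H = (a/b^2 + a/c^2)/2,
        # and cyclically for the other two axes
        a, b, c = 5.0, 3.0, 2.0
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.array([a, b, c]), rotation=np.eye(3)
        )
        pts = np.array([[a, 0, 0], [0, b, 0], [0, 0, c]])
        expected = np.array(
            [
                (a / b**2 + a / c**2) / 2,
                (b / a**2 + b / c**2) / 2,
                (c / a**2 + c / b**2) / 2,
            ]
        )
        np.testing.assert_allclose(model.mean_curvature(pts), expected, rtol=1e-12)

    def test_prolate_pole_dominates_equator(self):
        # curvature at the sharp pole of a prolate spheroid (a/b^2) exceeds
        # the equatorial value
        a, b = 10.0, 4.0
        model = EllipsoidModel(
            center=np.zeros(3), semi_axes=np.array([a, b, b]), rotation=np.eye(3)
        )
        H_pole = model.mean_curvature([[a, 0, 0]])[0]
        H_eq = model.mean_curvature([[0, b, 0]])[0]
        assert H_pole == pytest.approx(a / b**2, rel=1e-12)
        assert H_pole > H_eq

    def test_off_surface_points_use_radial_footpoint(self):
        model = sphere_model(100.0)
        inside = np.array([[30.0, 0, 0]])
        np.testing.assert_allclose(model.mean_curvature(inside), 0.01, rtol=1e-12)


@pytest.fixture(scope="module")
def report_parts():
    fx = generate_raft_fixture(2, 40, n_core_aggregate=25, seed=30, n_water=1500)
    feats = lipid_features(fx.frame)
    asg = cluster_lipids(feats, eps=12.0, min_samples=5)
    ell = fit_bounding_ellipsoid(fx.frame)
    rafts = identify_surface_rafts(asg, feats, ell)
    return fx, feats, asg, ell, rafts


class TestReport:
    def test_consistency_identity(self, report_parts):
        fx, feats, asg, ell, rafts = report_parts
        rep = build_surface_report(rafts, feats, ell, asg.labels)
        assert rep.coverage_percent == pytest.approx(100.0 * rep.excess_measured, abs=1e-9)

    def test_counts_match_fixture(self, report_parts):
        fx, feats, asg, ell, rafts = report_parts
        rep = build_surface_report(rafts, feats, ell, asg.labels)
        assert rep.n_total_fa == len(fx.true_labels)
        assert rep.n_surface_fa == int(fx.surface_mask.sum())

    def test_coverage_matches_planted_geometry(self, report_parts):
        # 80 surface lipids at 21 Å² each on a ~150 Å sphere: compare the
        # report against the closed-form percentage from the fitted area
        fx, feats, asg, ell, rafts = report_parts
        rep = build_surface_report(rafts, feats, ell, asg.labels)
        expected = 100.0 * 80 * rep.a_lipid / ell.surface_area()
        assert rep.coverage_percent == pytest.approx(expected, rel=1e-9)

    def test_weighted_mean_curvature_formula(self, report_parts):
        fx, feats, asg, ell, rafts = report_parts
        rep = build_surface_report(rafts, feats, ell, asg.labels)
        sizes = np.array([rep.raft_sizes[l] for l in rep.raft_curvatures])
        vals = np.array(list(rep.raft_curvatures.values()))
        assert rep.weighted_mean_curvature == pytest.approx(
            float((sizes * vals).sum() / sizes.sum()), rel=1e-12
        )
        # ~sphere of radius ~150+rod: curvature near 1/160
        assert rep.weighted_mean_curvature == pytest.approx(1 / 155.0, rel=0.1)

    def test_weighted_mean_hand_example(self):
        # two rafts of sizes 10 and 30 with curvatures 0.01 and 0.02
        sizes = np.array([10, 30])
        vals = np.array([0.01, 0.02])
        assert float((sizes * vals).sum() / sizes.sum()) == pytest.approx(0.0175)


class TestExposure:
    def test_surface_lipids_always_exposed(self):
        # rods standing on a sphere of radius R: tail beads sit at the outer
        # surface, so every molecule is exposed in every frame
        R = 100.0
        n = 16
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        normals = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
        mids = normals * R
        frame = lipid_frame(mids, normals, rod_length=10.0)
        model = sphere_model(R + 5.0)
        traj = static_trajectory(frame, 4)
        exp = residue_exposure(traj, np.ones(frame.n_beads, dtype=bool), model)
        np.testing.assert_allclose(exp.frequency, 1.0)

    def test_buried_molecules_never_exposed(self):
        mids = np.random.default_rng(2).normal(scale=3.0, size=(10, 3))
        orients = np.random.default_rng(3).normal(size=(10, 3))
        frame = lipid_frame(mids, orients, rod_length=2.0)
        model = sphere_model(200.0)
        traj = static_trajectory(frame, 5)
        exp = residue_exposure(traj, np.ones(frame.n_beads, dtype=bool), model, d_exp=3.0)
        np.testing.assert_allclose(exp.frequency, 0.0)

    def test_half_time_exposure(self):
        # a single molecule at the surface in frame 0 and buried in frame 1
        R = 50.0
        frame_out = lipid_frame(np.array([[R, 0, 0]]), np.array([[1.0, 0, 0]]), rod_length=2.0)
        coords_in = frame_out.coordinates * 0.1
        frame_in = frame_out.with_coordinates(coords_in, time=1.0)
        from aeromorph.frames import Trajectory

        traj = Trajectory(frames=[frame_out, frame_in], dt=1.0)
        exp = residue_exposure(traj, np.ones(frame_out.n_beads, dtype=bool), sphere_model(R))
        np.testing.assert_allclose(exp.frequency, [0.5])

    def test_one_ellipsoid_per_frame_required(self):
        frame = lipid_frame(np.array([[0.0, 0, 10]]), np.array([[0.0, 0, 1]]))
        traj = static_trajectory(frame, 3)
        with pytest.raises(ValueError, match="per frame"):
            residue_exposure(traj, np.ones(frame.n_beads, dtype=bool), [sphere_model(50.0)] * 2)
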