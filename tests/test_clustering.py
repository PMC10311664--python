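"""Raft clustering: features, DBSCAN behaviour, kinetics, surface rafts."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from aeromorph.clustering import (
    ClusterParams,
    cluster_lipids,
    clustering_kinetics,
    identify_surface_rafts,
    lipid_features,
)
from aeromorph.ellipsoid import EllipsoidModel, fit_bounding_ellipsoid
from aeromorph.frames import Trajectory
from aeromorph.generate import generate_raft_fixture

from conftest import lipid_frame, static_trajectory, uniform_ball


def dbscan_reference(X: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Brute-force DBSCAN oracle: pairwise distances + reachability BFS."""
    D = cdist(X, X)
    neigh = D <= eps
    core = neigh.sum(axis=1) >= min_samples
    labels = -np.ones(len(X), dtype=int)
    cid = 0
    for i in range(len(X)):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels


def grid_midpoints(n_side: int, spacing: float, z: float = 0.0) -> np.ndarray:
    xs = np.arange(n_side) * spacing
    gx, gy = np.meshgrid(xs, xs)
    return np.stack([gx.ravel(), gy.ravel(), np.full(n_side * n_side, z)], axis=1)


class TestLipidFeatures:
    def test_orientation_unit_vector(self):
        frame = lipid_frame(np.array([[0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, 2.0]]), rod_length=2.0)
        feats = lipid_features(frame)
        np.testing.assert_allclose(feats.orientations, [[0, 0, 1]], atol=1e-12)

    def test_zero_weight_reduces_to_positions(self, rng):
        mids = rng.normal(size=(8, 3))
        frame = lipid_frame(mids, rng.normal(size=(8, 3)))
        feats = lipid_features(frame, w=0.0)
        np.testing.assert_allclose(feats.feature_vectors[:, :3], feats.positions)
        np.testing.assert_allclose(feats.feature_vectors[:, 3:], 0.0)

    def test_antiparallel_distance_is_2w(self):
        mids = np.zeros((2, 3))
        orients = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        frame = lipid_frame(mids, orients)
        feats = lipid_features(frame, w=10.0)
        d = np.linalg.norm(feats.feature_vectors[0] - feats.feature_vectors[1])
        assert d == pytest.approx(20.0, abs=1e-9)

    def test_coincident_head_tail_rejected(self):
        frame = lipid_frame(np.zeros((1, 3)), np.array([[0.0, 0.0, 1.0]]), rod_length=0.0)
        with pytest.raises(ValueError, match="zero-length"):
            lipid_features(frame)


class TestClusterLipids:
    def test_two_separated_patches(self):
        a = grid_midpoints(8, 5.0)[:50]
        b = grid_midpoints(8, 5.0)[:50] + np.array([100.0, 0, 0])
        mids = np.concatenate([a, b])
        orients = np.tile([0.0, 0.0, 1.0], (100, 1))
        feats = lipid_features(lipid_frame(mids, orients))
        asg = cluster_lipids(feats, eps=15.0, min_samples=5)
        assert asg.n_clusters == 2
        assert asg.fraction_clustered == 1.0

    def test_sparse_grid_all_noise(self):
        eps = 4.0
        mids = grid_midpoints(5, 3 * eps)
        orients = np.tile([0.0, 0.0, 1.0], (25, 1))
        feats = lipid_features(lipid_frame(mids, orients))
        asg = cluster_lipids(feats, eps=eps, min_samples=3)
        assert asg.n_clusters == 0
        assert asg.fraction_clustered == 0.0
        assert np.all(asg.labels == -1)

    def test_orientation_split_resolves_antiparallel_halves(self):
        # one spatial patch, two antiparallel halves; 2w > eps > spacing
        mids = grid_midpoints(6, 4.0)
        orients = np.tile([0.0, 0.0, 1.0], (36, 1))
        orients[18:] *= -1.0
        feats = lipid_features(lipid_frame(mids, orients), w=10.0)
        asg = cluster_lipids(feats, eps=10.0, min_samples=4)
        assert asg.n_clusters == 2
        ref = dbscan_reference(feats.feature_vectors, eps=10.0, min_samples=4)
        assert adjusted_rand_score(ref, asg.labels) == 1.0

    def test_matches_reference_on_planted_fixture(self):
        fx = generate_raft_fixture(3, 30, seed=11, n_water=200)
        feats = lipid_features(fx.frame, w=10.0)
        asg = cluster_lipids(feats, eps=12.0, min_samples=5)
        ref = dbscan_reference(feats.feature_vectors, eps=12.0, min_samples=5)
        assert adjusted_rand_score(ref, asg.labels) == 1.0

    def test_planted_raft_recovery_exact(self):
        # aggregate_radius is chosen so the 20-lipid core satisfies the DBSCAN
        # density precondition (expected eps-ball occupancy well above
        # min_samples even at the aggregate edge); sparser aggregates are not
        # guaranteed to be recovered without noise
        fx = generate_raft_fixture(
            4, 25, n_core_aggregate=20, seed=12, n_water=100, aggregate_radius=10.0
        )
        feats = lipid_features(fx.frame, w=10.0)
        asg = cluster_lipids(feats, eps=12.0, min_samples=5)
        assert adjusted_rand_score(fx.true_labels, asg.labels) == 1.0

    def test_partition_property(self):
        fx = generate_raft_fixture(2, 30, seed=13)
        feats = lipid_features(fx.frame)
        asg = cluster_lipids(feats)
        assert len(asg.labels) == len(fx.frame.surfactant_ids)

    def test_noise_count_monotone_in_eps(self):
        fx = generate_raft_fixture(3, 20, n_core_aggregate=10, seed=14)
        feats = lipid_features(fx.frame)
        noise = [
            int((cluster_lipids(feats, eps=e, min_samples=5).labels == -1).sum())
            for e in (4.0, 6.0, 8.0, 12.0, 20.0)
        ]
        assert all(a >= b for a, b in zip(noise, noise[1:]))

    def test_empty_feature_set_rejected(self):
        fx = generate_raft_fixture(1, 10, seed=15)
        feats = lipid_features(fx.frame)
        feats.feature_vectors = feats.feature_vectors[:0]
        feats.molecule_ids = feats.molecule_ids[:0]
        with pytest.raises(ValueError):
            cluster_lipids(feats)


class TestKinetics:
    def test_static_trajectory_constant_series(self):
        fx = generate_raft_fixture(2, 30, seed=16)
        traj = static_trajectory(fx.frame, 4)
        series = clustering_kinetics(traj)
        assert len(series) == 4
        assert len({a.n_clusters for a in series}) == 1
        assert len({a.fraction_clustered for a in series}) == 1

    def test_patch_dispersal_drops_cluster_count(self, rng):
        fx = generate_raft_fixture(2, 30, seed=17)
        frame0 = fx.frame
        # disperse the second patch's lipids far apart in the second frame
        coords = frame0.coordinates.copy()
        victims = np.flatnonzero(fx.true_labels == 1)
        for i, v in enumerate(victims):
            shift = np.array([4000.0 * (i + 1), 0.0, 0.0])
            coords[frame0.head_indices[v]] += shift
            coords[frame0.tail_indices[v]] += shift
        traj = Trajectory(
            frames=[frame0, frame0.with_coordinates(coords, time=1.0)], dt=1.0
        )
        series = clustering_kinetics(traj)
        assert series[1].n_clusters == series[0].n_clusters - 1

    def test_labels_stable_under_jitter_with_matching(self, rng):
        fx = generate_raft_fixture(3, 30, seed=18)
        frames = [fx.frame]
        for k in range(1, 4):
            jitter = rng.normal(scale=0.3, size=fx.frame.coordinates.shape)
            frames.append(fx.frame.with_coordinates(fx.frame.coordinates + jitter, time=float(k)))
        traj = Trajectory(frames=frames, dt=1.0)
        series = clustering_kinetics(traj, ClusterParams(match_across_frames=True))
        for a in series[1:]:
            np.testing.assert_array_equal(a.labels, series[0].labels)


@pytest.fixture(scope="module")
def fixture_and_parts():
    fx = generate_raft_fixture(2, 40, n_core_aggregate=25, seed=19, n_water=1500)
    feats = lipid_features(fx.frame)
    asg = cluster_lipids(feats, eps=12.0, min_samples=5)
    ell = fit_bounding_ellipsoid(fx.frame)
    return fx, feats, asg, ell


class TestSurfaceRafts:
    def test_planted_patches_classified_surface(self, fixture_and_parts):
        fx, feats, asg, ell = fixture_and_parts
        rafts = identify_surface_rafts(asg, feats, ell)
        assert len(rafts.raft_labels) == 2
        assert rafts.member_mask.sum() == 80

    def test_core_aggregate_excluded(self, fixture_and_parts):
        fx, feats, asg, ell = fixture_and_parts
        rafts = identify_surface_rafts(asg, feats, ell)
        core_lipids = np.flatnonzero(fx.true_labels == 2)
        assert not rafts.member_mask[core_lipids].any()

    def test_tilted_patch_fails_alignment(self):
        fx = generate_raft_fixture(1, 40, patch_tilt=85.0, seed=20, n_water=1500)
        feats = lipid_features(fx.frame)
        asg = cluster_lipids(feats, eps=12.0, min_samples=5)
        ell = fit_bounding_ellipsoid(fx.frame)
        rafts = identify_surface_rafts(asg, feats, ell, align_min=0.5)
        # cos(85 deg) ~ 0.087 < 0.5: the patch sits at the surface but is not
        # outward-aligned, so it is not a raft
        assert rafts.raft_labels == []
        assert max(rafts.raft_alignment.values()) < 0.5
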