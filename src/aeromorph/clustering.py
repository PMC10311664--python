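"""Density-based clustering of surfactants into rafts.

Each surfactant contributes a 6-D feature vector: its centroid position
(x, y, z, in Å) concatenated with its unit head->tail orientation scaled by a
weight w (also in Å), so that plain Euclidean DBSCAN sees both where a lipid
is and which way it points. Two co-located but antiparallel lipids are 2w
apart in feature space; choosing 2w > eps therefore separates oppositely
tilted monolayer patches, which is how tessellated rafts with distinct tilt
are resolved. Lipids not absorbed into any cluster keep the DBSCAN noise
label -1 ("unclustered").

Surface rafts are the clusters whose centroid sits in the outermost
equal-volume shell of the fitted bounding ellipsoid and whose mean
orientation points outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .ellipsoid import EllipsoidModel
from .frames import ParticleFrame, Trajectory

#: default DBSCAN reachability radius, Å (2-3 condensed-monolayer spacings)
DEFAULT_EPS = 12.0
DEFAULT_MIN_SAMPLES = 5
#: default orientation weight, Å: a head-to-tail flip costs 2w = 20 Å
DEFAULT_ORIENTATION_WEIGHT = 10.0
#: outermost equal-volume shell boundary, (2/3)^(1/3)
DEFAULT_U_MIN = (2.0 / 3.0) ** (1.0 / 3.0)
DEFAULT_ALIGN_MIN = 0.5


@dataclass
class LipidFeatures:
    """Per-surfactant positions, orientations and stacked feature vectors."""

    molecule_ids: np.ndarray
    positions: np.ndarray  # (n, 3) centroids, Å
    orientations: np.ndarray  # (n, 3) unit head->tail vectors
    feature_vectors: np.ndarray  # (n, 6)
    orientation_weight: float

    def __len__(self) -> int:
        return len(self.molecule_ids)


@dataclass
class ClusterAssignment:
    """DBSCAN labels per surfactant; -1 means unclustered."""

    labels: np.ndarray
    time: float = 0.0
    n_clusters: int = field(init=False)
    fraction_clustered: float = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        clustered = self.labels >= 0
        self.n_clusters = len(np.unique(self.labels[clustered])) if clustered.any() else 0
        self.fraction_clustered = float(clustered.mean()) if len(self.labels) else 0.0

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def lipid_features(
    frame: ParticleFrame, w: float = DEFAULT_ORIENTATION_WEIGHT
) -> LipidFeatures:
    """Build clustering features for every surfactant in a frame.

    Raises
    ------
    ValueError
        If the frame has no surfactants or a lipid has coincident head and
        tail beads (zero-length orientation vector).
    """
    if len(frame.surfactant_ids) == 0:
        raise ValueError("frame has no surfactant molecules")
    heads = frame.coordinates[frame.head_indices]
    tails = frame.coordinates[frame.tail_indices]
    vec = tails - heads
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms == 0):
        bad = frame.surfactant_ids[norms == 0]
        raise ValueError(f"zero-length head->tail vector for molecules {bad[:5].tolist()}")
    orient = vec / norms[:, None]

    # molecule centroid over all of the molecule's beads (vectorized groupby)
    uniq, inverse = np.unique(frame.molecule_id, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inverse, frame.coordinates)
    counts = np.bincount(inverse, minlength=len(uniq))
    centroids = sums / counts[:, None]
    idx = np.searchsorted(uniq, frame.surfactant_ids)
    positions = centroids[idx]

    features = np.hstack([positions, w * orient])
    return LipidFeatures(
        molecule_ids=frame.surfactant_ids.copy(),
        positions=positions,
        orientations=orient,
        feature_vectors=features,
        orientation_weight=w,
    )


def cluster_lipids(
    features: LipidFeatures,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    time: float = 0.0,
) -> ClusterAssignment:
    """Euclidean DBSCAN over the 6-D features; noise labelled -1."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(features) == 0:
        raise ValueError("empty feature set")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(features.feature_vectors)
    return ClusterAssignment(labels=labels, time=time)


@dataclass(frozen=True)
class ClusterParams:
    eps: float = DEFAULT_EPS
    min_samples: int = DEFAULT_MIN_SAMPLES
    orientation_weight: float = DEFAULT_ORIENTATION_WEIGHT
    match_across_frames: bool = True


def _match_labels(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Relabel ``cur`` clusters to maximize molecule overlap with ``prev``.

    Greedy: largest shared-membership pairs claim identities first; clusters
    with no overlap get fresh labels. Noise stays -1.
    """
    cur_ids = [c for c in np.unique(cur) if c >= 0]
    prev_ids = [c for c in np.unique(prev) if c >= 0]
    overlaps = []
    for c in cur_ids:
        for p in prev_ids:
            ov = int(np.sum((cur == c) & (prev == p)))
            if ov:
                overlaps.append((ov, c, p))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for ov, c, p in overlaps:
        if c not in mapping and p not in used:
            mapping[c] = p
            used.add(p)
    fresh = (max(prev_ids, default=-1)) + 1
    out = cur.copy()
    for c in cur_ids:
        if c not in mapping:
            mapping[c] = fresh
            fresh += 1
        out[cur == c] = mapping[c]
    return out


def clustering_kinetics(
    traj: Trajectory, params: ClusterParams = ClusterParams()
) -> list[ClusterAssignment]:
    """Per-frame cluster assignments, optionally identity-matched over time."""
    out: list[ClusterAssignment] = []
    prev: np.ndarray | None = None
    for i, frame in enumerate(traj):
        try:
            feats = lipid_features(frame, w=params.orientation_weight)
            assignment = cluster_lipids(feats, params.eps, params.min_samples, time=frame.time)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        if params.match_across_frames and prev is not None:
            assignment = ClusterAssignment(
                labels=_match_labels(prev, assignment.labels), time=frame.time
            )
        prev = assignment.labels
        out.append(assignment)
    return out


@dataclass
class SurfaceRafts:
    """Clusters identified as surface monolayer rafts."""

    raft_labels: list[int]
    raft_sizes: dict[int, int]
    raft_u: dict[int, float]
    raft_alignment: dict[int, float]
    member_mask: np.ndarray  # per-surfactant: member of any surface raft


def identify_surface_rafts(
    assignment: ClusterAssignment,
    features: LipidFeatures,
    ellipsoid: EllipsoidModel,
    u_min: float = DEFAULT_U_MIN,
    align_min: float = DEFAULT_ALIGN_MIN,
) -> SurfaceRafts:
    """Select clusters that are monolayer rafts at the particle surface.

    A cluster qualifies iff (i) its centroid's ellipsoidal coordinate u is at
    least ``u_min`` (default: the outermost equal-volume shell) and (ii) the
    mean cosine between its members' head->tail orientations and the outward
    ellipsoid normal is at least ``align_min`` (tails to the vacuum).
    """
    raft_labels: list[int] = []
    sizes: dict[int, int] = {}
    us: dict[int, float] = {}
    aligns: dict[int, float] = {}
    member_mask = np.zeros(len(features), dtype=bool)
    for label in sorted(set(assignment.labels[assignment.labels >= 0])):
        members = assignment.members(label)
        centroid = features.positions[members].mean(axis=0)
        if np.allclose(centroid, ellipsoid.center):
            raise ValueError(f"cluster {label}: centroid at ellipsoid centre, normal undefined")
        u_c = float(ellipsoid.u(centroid)[0])
        normals = ellipsoid.outward_normal(features.positions[members])
        align = float(np.mean(np.einsum("ij,ij->i", features.orientations[members], normals)))
        sizes[label] = len(members)
        us[label] = u_c
        aligns[label] = align
        if u_c >= u_min and align >= align_min:
            raft_labels.append(label)
            member_mask[members] = True
    return SurfaceRafts(
        raft_labels=raft_labels,
        raft_sizes=sizes,
        raft_u=us,
        raft_alignment=aligns,
        member_mask=member_mask,
    )
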