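"""Surface coverage, surface excess, raft curvature and atmospheric exposure.

The particle surface is the fitted bounding ellipsoid. Its area A (Thomsen's
approximation) divided by the area per lipid a_lipid defines the number of
available surface "sites", N_sites = A / a_lipid. Then

* coverage (%)       = 100 * n_surface_lipids * a_lipid / A,
* surface excess     = lipid count / N_sites, either *predicted* from every
  fatty acid in the system or *measured* from those actually resident in
  surface rafts. A value of 1 means exactly as many lipids as sites; > 1 a
  surplus, < 1 a deficit.

Raft curvature is the mean curvature H of the analytic ellipsoid surface at
each member's radial footpoint, averaged per raft and then combined across
rafts weighted by raft size. Atmospheric exposure of a residue (molecule) is
the fraction of frames in which any of its beads comes within d_exp of the
outer surface along its own radial direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import LipidFeatures, SurfaceRafts
from .ellipsoid import EllipsoidModel
from .frames import Trajectory

#: default area per lipid, Å² (condensed saturated fatty-acid monolayer)
DEFAULT_AREA_PER_LIPID = 21.0
#: default exposure distance threshold, Å
DEFAULT_D_EXP = 3.0


@dataclass
class SurfaceReport:
    A_surface: float  # Å²
    a_lipid: float  # Å²
    n_sites: float
    n_total_fa: int
    n_surface_fa: int
    coverage_percent: float
    excess_predicted: float
    excess_measured: float
    raft_sizes: dict[int, int]
    raft_curvatures: dict[int, float]  # Å⁻¹
    weighted_mean_curvature: float | None


def surface_sites(ellipsoid: EllipsoidModel, a_lipid: float = DEFAULT_AREA_PER_LIPID) -> float:
    """Number of available lipid sites on the ellipsoid surface."""
    if a_lipid <= 0:
        raise ValueError("a_lipid must be positive")
    return ellipsoid.surface_area() / a_lipid


def surface_coverage(
    n_surface_fa: int,
    ellipsoid: EllipsoidModel,
    a_lipid: float = DEFAULT_AREA_PER_LIPID,
) -> float:
    """Percent of the ellipsoid surface covered by surface-raft lipids."""
    area = ellipsoid.surface_area()
    if area <= 0:
        raise ValueError("zero surface area")
    return 100.0 * n_surface_fa * a_lipid / area


def surface_excess(
    n_total_fa: int,
    n_surface_fa: int,
    ellipsoid: EllipsoidModel,
    a_lipid: float = DEFAULT_AREA_PER_LIPID,
) -> tuple[float, float]:
    """(predicted, measured) surface excess relative to available sites."""
    if n_total_fa < 0 or n_surface_fa < 0:
        raise ValueError("counts must be nonnegative")
    sites = surface_sites(ellipsoid, a_lipid)
    return n_total_fa / sites, n_surface_fa / sites


def raft_curvature(
    rafts: SurfaceRafts,
    features: LipidFeatures,
    ellipsoid: EllipsoidModel,
    assignment_labels: np.ndarray,
) -> tuple[dict[int, float], float | None]:
    """Per-raft mean curvature and the raft-size-weighted system mean, Å⁻¹."""
    curvatures: dict[int, float] = {}
    for label in rafts.raft_labels:
        members = np.flatnonzero(assignment_labels == label)
        H = ellipsoid.mean_curvature(features.positions[members])
        curvatures[label] = float(H.mean())
    if not curvatures:
        return curvatures, None
    sizes = np.array([rafts.raft_sizes[l] for l in curvatures])
    values = np.array(list(curvatures.values()))
    return curvatures, float(np.sum(sizes * values) / sizes.sum())


def build_surface_report(
    rafts: SurfaceRafts,
    features: LipidFeatures,
    ellipsoid: EllipsoidModel,
    assignment_labels: np.ndarray,
    a_lipid: float = DEFAULT_AREA_PER_LIPID,
) -> SurfaceReport:
    """Assemble coverage, excess and curvature into one report.

    The coverage/excess consistency identity
    ``coverage_percent == 100 * excess_measured`` holds by construction when
    both use the same raft set and a_lipid.
    """
    n_total = len(features)
    n_surface = int(rafts.member_mask.sum())
    coverage = surface_coverage(n_surface, ellipsoid, a_lipid)
    predicted, measured = surface_excess(n_total, n_surface, ellipsoid, a_lipid)
    curv, weighted = raft_curvature(rafts, features, ellipsoid, assignment_labels)
    sizes = {l: rafts.raft_sizes[l] for l in rafts.raft_labels}
    return SurfaceReport(
        A_surface=ellipsoid.surface_area(),
        a_lipid=a_lipid,
        n_sites=surface_sites(ellipsoid, a_lipid),
        n_total_fa=n_total,
        n_surface_fa=n_surface,
        coverage_percent=coverage,
        excess_predicted=predicted,
        excess_measured=measured,
        raft_sizes=sizes,
        raft_curvatures=curv,
        weighted_mean_curvature=weighted,
    )


@dataclass
class ExposureMap:
    molecule_ids: np.ndarray
    frequency: np.ndarray  # in [0, 1], per molecule
    d_exp: float

    def as_dict(self) -> dict[int, float]:
        return {int(m): float(f) for m, f in zip(self.molecule_ids, self.frequency)}


def residue_exposure(
    traj: Trajectory,
    selection,
    ellipsoids: list[EllipsoidModel] | EllipsoidModel,
    d_exp: float = DEFAULT_D_EXP,
) -> ExposureMap:
    """Frequency of atmospheric exposure per molecule over a trajectory.

    A bead is exposed in a frame when its distance to the particle surface
    along its own radial direction is at most ``d_exp``: with R_dir the
    centre-to-surface distance along the bead's ray, the criterion is
    ``u >= 1 - d_exp / R_dir`` (beads outside the ellipsoid are exposed). A
    molecule is exposed when any of its beads is.

    ``ellipsoids`` is either one model reused for all frames or one per frame.
    """
    frame0 = traj[0]
    if isinstance(selection, str):
        mask = frame0.select(selection)
    else:
        mask = np.asarray(selection, dtype=bool)
    if not mask.any():
        raise ValueError("selection is empty")
    if isinstance(ellipsoids, EllipsoidModel):
        ellipsoids = [ellipsoids] * len(traj)
    if len(ellipsoids) != len(traj):
        raise ValueError("need one ellipsoid per frame (or a single shared model)")

    mol_of_bead = frame0.molecule_id[mask]
    mol_ids = np.unique(mol_of_bead)
    idx = np.searchsorted(mol_ids, mol_of_bead)
    exposed_frames = np.zeros(len(mol_ids))
    for frame, ell in zip(traj, ellipsoids):
        pts = frame.coordinates[mask]
        uu = ell.u(pts)
        radial = np.linalg.norm(pts - ell.center, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_dir = np.where(uu > 0, radial / np.where(uu > 0, uu, 1.0), np.inf)
        exposed_bead = uu >= 1.0 - d_exp / r_dir
        exposed_mol = np.zeros(len(mol_ids), dtype=bool)
        np.logical_or.at(exposed_mol, idx, exposed_bead)
        exposed_frames += exposed_mol
    return ExposureMap(
        molecule_ids=mol_ids, frequency=exposed_frames / len(traj), d_exp=d_exp
    )
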