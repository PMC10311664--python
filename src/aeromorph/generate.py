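"""Synthetic particle and trajectory generators.

These generators provide ground truth for every analysis stage: a randomly
packed droplet realizing a :class:`~aeromorph.composition.CompositionSpec`,
a particle with planted surfactant rafts of known membership and tilt, and an
overdamped Brownian water trajectory with a known, possibly shell-dependent,
diffusion coefficient.

All randomness flows through a single integer seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import (
    ComponentSpec,
    CompositionSpec,
    ION_MASSES,
    MoleculeCounts,
    WATER,
)
from .frames import ParticleFrame, Trajectory


class GenerationError(RuntimeError):
    """Raised when a requested geometry cannot be realized."""


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform samples inside a sphere by rejection from the bounding cube."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - filled) + 16, 3))
        keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius * radius]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


#: default head-to-tail rod length for a 2-bead fatty acid, Å
FA_ROD_LENGTH = 12.0
#: bead-to-bead spacing within multi-bead molecules, Å
POLYMER_BEAD_SPACING = 5.0


def generate_particle(
    comp: CompositionSpec,
    counts: MoleculeCounts,
    seed: int,
    *,
    rod_length: float = FA_ROD_LENGTH,
) -> ParticleFrame:
    """Randomly pack a particle realizing ``counts`` inside its sphere.

    Molecule centres are drawn uniformly in the sphere of the design diameter.
    Surfactants become 2-bead rods with a random orientation (head->tail);
    multi-bead molecules become short rods/blobs of beads around the centre.
    Molar mass is split evenly over a molecule's beads.
    """
    rng = np.random.default_rng(seed)
    radius = comp.particle_diameter / 2.0

    coords: list[np.ndarray] = []
    masses: list[np.ndarray] = []
    mol_ids: list[np.ndarray] = []
    classes: list[np.ndarray] = []
    surf_ids: list[int] = []
    heads: list[int] = []
    tails: list[int] = []

    next_mol = 0
    next_bead = 0

    def emit(n_mol: int, spec: ComponentSpec) -> None:
        nonlocal next_mol, next_bead
        if n_mol == 0:
            return
        centres = _uniform_ball(rng, n_mol, radius)
        nb = spec.beads_per_molecule
        if nb == 1:
            pos = centres
        else:
            axes = _unit_vectors(rng, n_mol)
            length = rod_length if spec.head_tail_defined else (nb - 1) * POLYMER_BEAD_SPACING
            offsets = np.linspace(-0.5, 0.5, nb) * length
            pos = (centres[:, None, :] + offsets[None, :, None] * axes[:, None, :]).reshape(-1, 3)
        coords.append(pos)
        masses.append(np.full(n_mol * nb, spec.molar_mass / nb))
        mol_ids.append(np.repeat(np.arange(next_mol, next_mol + n_mol), nb))
        classes.append(np.full(n_mol * nb, spec.component_class, dtype="U12"))
        if spec.head_tail_defined:
            # bead 0 of the rod is the head (carboxyl end), last bead the tail
            surf_ids.extend(range(next_mol, next_mol + n_mol))
            heads.extend(next_bead + nb * np.arange(n_mol))
            tails.extend(next_bead + nb * np.arange(n_mol) + nb - 1)
        next_mol += n_mol
        next_bead += n_mol * nb

    for name in sorted(counts.counts):
        n = counts.counts[name]
        if name in comp.components:
            emit(n, comp.components[name])
        elif name == "water":
            emit(n, WATER)
        elif name in ION_MASSES:
            emit(n, ComponentSpec(name, "ion", ION_MASSES[name]))
        else:  # pragma: no cover - counts always come from build_composition
            raise GenerationError(f"no component spec for {name!r}")

    return ParticleFrame(
        coordinates=np.concatenate(coords),
        masses=np.concatenate(masses),
        molecule_id=np.concatenate(mol_ids),
        component_class=np.concatenate(classes),
        surfactant_ids=np.array(surf_ids, dtype=np.int64),
        head_indices=np.array(heads, dtype=np.int64),
        tail_indices=np.array(tails, dtype=np.int64),
    )


@dataclass
class RaftFixture:
    """A planted-raft particle with ground truth.

    ``true_labels`` gives, per surfactant molecule (in ``frame.surfactant_ids``
    order), the planted patch index (0..n_patches-1) or ``n_patches`` for the
    core aggregate. ``surface_mask`` marks surfactants planted at the surface.
    """

    frame: ParticleFrame
    true_labels: np.ndarray
    surface_mask: np.ndarray
    patch_centers: np.ndarray
    radius: float


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _disc_grid(n: int, spacing: float) -> np.ndarray:
    """n points on a sunflower-spiral disc with the given mean spacing."""
    k = np.arange(n) + 0.5
    r = spacing * np.sqrt(k / np.pi)
    theta = k * (np.pi * (3.0 - np.sqrt(5.0)))
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def generate_raft_fixture(
    n_patches: int,
    lipids_per_patch: int,
    patch_tilt: float | list[float] = 0.0,
    n_core_aggregate: int = 0,
    seed: int = 0,
    *,
    radius: float = 150.0,
    lipid_spacing: float = 5.0,
    rod_length: float = FA_ROD_LENGTH,
    n_water: int = 2000,
    aggregate_radius: float = 20.0,
    min_separation_factor: float = 2.5,
    max_attempts: int = 5000,
) -> RaftFixture:
    """Plant monolayer patches of known tilt on a spherical droplet.

    Each patch is a disc of 2-bead lipids on the sphere surface; at zero tilt
    every lipid points along the outward normal, tails to the vacuum and heads
    to the aqueous interior (the monolayer convention). The optional core
    aggregate is a dense blob of co-aligned lipids at the centre. Water filler
    beads make the droplet a solid ball so that ellipsoid fitting sees the
    full body.

    Raises
    ------
    GenerationError
        If the patches cannot be placed with the required angular separation.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(patch_tilt):
        tilts = np.full(n_patches, float(patch_tilt))
    else:
        tilts = np.asarray(patch_tilt, dtype=float)
        if len(tilts) != n_patches:
            raise ValueError("patch_tilt must be scalar or one value per patch")

    patch_radius = lipid_spacing * np.sqrt(lipids_per_patch / np.pi)
    min_angle = min_separation_factor * patch_radius / radius
    if n_patches * (min_angle / 2) ** 2 > 4:  # crude cap-area feasibility bound
        raise GenerationError("patches cannot fit on the sphere at this spacing")

    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_patches:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not place {n_patches} patches with angular separation "
                f">= {np.degrees(min_angle):.1f} deg after {max_attempts} attempts"
            )
        cand = _unit_vectors(rng, 1)[0]
        if all(np.arccos(np.clip(cand @ c, -1, 1)) > min_angle for c in centers):
            centers.append(cand)
        attempts += 1
    patch_centers = np.array(centers)

    coords: list[np.ndarray] = []
    labels: list[int] = []
    surface: list[bool] = []

    for p in range(n_patches):
        normal = patch_centers[p]
        e1, e2 = _tangent_basis(normal)
        grid = _disc_grid(lipids_per_patch, lipid_spacing)
        # project the flat disc onto the sphere surface
        mids = radius * _normalize(normal[None, :] * radius + grid[:, 0:1] * e1 + grid[:, 1:2] * e2)
        local_normals = mids / radius
        # tilt: rotate the outward normal about the local e1 axis
        c, s = np.cos(np.radians(tilts[p])), np.sin(np.radians(tilts[p]))
        directions = c * local_normals + s * np.cross(e1, local_normals) * -1.0
        directions = _normalize(directions)
        head = mids - 0.5 * rod_length * directions
        tail = mids + 0.5 * rod_length * directions
        coords.append(np.stack([head, tail], axis=1).reshape(-1, 3))
        labels.extend([p] * lipids_per_patch)
        surface.extend([True] * lipids_per_patch)

    if n_core_aggregate:
        mids = _uniform_ball(rng, n_core_aggregate, aggregate_radius)
        direction = _unit_vectors(rng, 1)[0]
        head = mids - 0.5 * rod_length * direction
        tail = mids + 0.5 * rod_length * direction
        coords.append(np.stack([head, tail], axis=1).reshape(-1, 3))
        labels.extend([n_patches] * n_core_aggregate)
        surface.extend([False] * n_core_aggregate)

    n_lipids = len(labels)
    lipid_coords = np.concatenate(coords) if coords else np.empty((0, 3))
    water_coords = _uniform_ball(rng, n_water, radius)

    lipid_mass = 256.4 / 2.0  # palmitic-acid-like rods, mass split over 2 beads
    coordinates = np.concatenate([lipid_coords, water_coords])
    masses = np.concatenate(
        [np.full(2 * n_lipids, lipid_mass), np.full(n_water, WATER.molar_mass)]
    )
    molecule_id = np.concatenate(
        [np.repeat(np.arange(n_lipids), 2), np.arange(n_lipids, n_lipids + n_water)]
    )
    component_class = np.concatenate(
        [np.full(2 * n_lipids, "fatty_acid", dtype="U12"), np.full(n_water, "water", dtype="U12")]
    )
    frame = ParticleFrame(
        coordinates=coordinates,
        masses=masses,
        molecule_id=molecule_id,
        component_class=component_class,
        surfactant_ids=np.arange(n_lipids),
        head_indices=2 * np.arange(n_lipids),
        tail_indices=2 * np.arange(n_lipids) + 1,
    )
    return RaftFixture(
        frame=frame,
        true_labels=np.array(labels, dtype=np.int64),
        surface_mask=np.array(surface, dtype=bool),
        patch_centers=patch_centers,
        radius=radius,
    )


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_brownian_trajectory(
    frame: ParticleFrame,
    shell_D: list[tuple[tuple[float, float], float]],
    dt: float,
    n_frames: int,
    seed: int = 0,
    *,
    boundary_radius: float | None = None,
    center: np.ndarray | None = None,
) -> Trajectory:
    """Overdamped random walk for water beads with shell-dependent diffusivity.

    ``shell_D`` is a list of ``((r_lo, r_hi), D)`` radius bands in Å with the
    diffusion coefficient in Å²/ns; the bands must cover every water bead's
    radius at every step. At each step a water takes a Gaussian displacement
    with per-axis variance ``2 D(r) dt`` using the D of the band that contains
    it at the step start. Walkers reflect off the sphere of
    ``boundary_radius`` (default: the outermost band edge). Non-water beads
    stay put.

    Raises
    ------
    ValueError
        For a negative D, non-positive dt, or a water bead outside all bands.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not shell_D:
        raise ValueError("shell_D must list at least one band")
    edges = np.array([[lo, hi] for (lo, hi), _ in shell_D])
    Ds = np.array([d for _, d in shell_D])
    if np.any(Ds < 0):
        raise ValueError("diffusion coefficients must be nonnegative")
    r_max = edges[:, 1].max()
    if boundary_radius is None:
        boundary_radius = r_max

    rng = np.random.default_rng(seed)
    water = frame.select("water")
    if center is None:
        center = frame.centroid()
    else:
        center = np.asarray(center, dtype=np.float64)
    pos = frame.coordinates[water].copy()

    def band_D(radii: np.ndarray) -> np.ndarray:
        out = np.full(len(radii), -1.0)
        for (lo, hi), d in zip(edges, Ds):
            inside = (radii >= lo) & (radii <= hi) & (out < 0)
            out[inside] = d
        if np.any(out < 0):
            bad = radii[out < 0]
            raise ValueError(
                f"{len(bad)} water beads outside all shell bands "
                f"(radii up to {bad.max():.1f} Å)"
            )
        return out

    frames = [frame.with_coordinates(frame.coordinates.copy(), time=frame.time)]
    current = frame.coordinates.copy()
    for k in range(1, n_frames):
        # displacements act on absolute coordinates; only the radii are
        # measured relative to the centre, so a zero-D walker is exactly static
        radii = np.linalg.norm(pos - center, axis=1)
        sigma = np.sqrt(2.0 * band_D(radii) * dt)
        pos = pos + rng.normal(size=pos.shape) * sigma[:, None]
        # radial reflection off the bounding sphere
        rel = pos - center
        r_new = np.linalg.norm(rel, axis=1)
        out = r_new > boundary_radius
        if np.any(out):
            pos[out] = center + rel[out] * (
                (2 * boundary_radius - r_new[out]) / r_new[out]
            )[:, None]
        current = current.copy()
        current[water] = pos
        frames.append(frame.with_coordinates(current, time=frame.time + k * dt))
    return Trajectory(frames=frames, dt=dt)
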