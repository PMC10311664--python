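"""Core in-memory containers for particle snapshots and trajectories.

Coordinates are stored in Angstrom, masses in amu, times in ns, regardless of
the native units of any file format they came from. A droplet in vacuum is
non-periodic: the box edge is carried as metadata only and never used for
minimum-image conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: The component classes every bead must belong to.
COMPONENT_CLASSES = ("fatty_acid", "protein", "lps", "saccharide", "water", "ion")

#: Classes counted as "organic" in mass-distribution reports.
ORGANIC_CLASSES = ("fatty_acid", "protein", "lps", "saccharide")


@dataclass
class ParticleFrame:
    """One snapshot of a coarse-grained particle.

    Parameters
    ----------
    coordinates : (N, 3) float array, Angstrom
    masses : (N,) float array, amu
    molecule_id : (N,) int array
        Beads sharing an id belong to one molecule.
    component_class : (N,) str array
        One of :data:`COMPONENT_CLASSES` per bead.
    surfactant_ids, head_indices, tail_indices : int arrays, parallel
        For every surfactant molecule (head/tail defined), the molecule id and
        the bead indices of its head and tail bead. The head->tail vector is
        the orientation used by the raft clustering.
    time : float, ns
    """

    coordinates: np.ndarray
    masses: np.ndarray
    molecule_id: np.ndarray
    component_class: np.ndarray
    surfactant_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    head_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tail_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.component_class = np.asarray(self.component_class)
        self.surfactant_ids = np.asarray(self.surfactant_ids, dtype=np.int64)
        self.head_indices = np.asarray(self.head_indices, dtype=np.int64)
        self.tail_indices = np.asarray(self.tail_indices, dtype=np.int64)
        n = len(self.coordinates)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive and match coordinates")
        if self.molecule_id.shape != (n,) or self.component_class.shape != (n,):
            raise ValueError("per-bead arrays must match coordinates length")
        unknown = set(np.unique(self.component_class)) - set(COMPONENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown component classes: {sorted(unknown)}")
        if not (len(self.surfactant_ids) == len(self.head_indices) == len(self.tail_indices)):
            raise ValueError("surfactant id/head/tail arrays must be parallel")
        for idx in (self.head_indices, self.tail_indices):
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError("head/tail indices out of range")

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def centroid(self, mass_weighted: bool = True) -> np.ndarray:
        """Centre of the frame (mass-weighted by default), Angstrom."""
        if mass_weighted:
            return self.masses @ self.coordinates / self.masses.sum()
        return self.coordinates.mean(axis=0)

    def select(self, classes: str | Sequence[str]) -> np.ndarray:
        """Boolean mask of beads whose component class is in ``classes``."""
        if isinstance(classes, str):
            classes = (classes,)
        return np.isin(self.component_class, list(classes))

    def with_coordinates(self, coordinates: np.ndarray, time: float | None = None) -> "ParticleFrame":
        """Copy of this frame with new coordinates (same topology)."""
        return replace(
            self,
            coordinates=np.asarray(coordinates, dtype=np.float64),
            time=self.time if time is None else time,
        )


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    frames: list[ParticleFrame]
    dt: float
    box_edge: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.frames[0].n_beads
        times = [f.time for f in self.frames]
        for f in self.frames:
            if f.n_beads != n:
                raise ValueError("atom count must be constant across frames")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ParticleFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> ParticleFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, N_sel, 3)."""
        if mask is None:
            return np.stack([f.coordinates for f in self.frames])
        return np.stack([f.coordinates[mask] for f in self.frames])
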