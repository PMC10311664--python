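"""Reading and writing standard coordinate/trajectory formats.

MDAnalysis does the format work (PDB/GRO/XYZ coordinates; DCD/XTC
trajectories); this module binds files to :class:`ParticleFrame` /
:class:`Trajectory` objects through a *component map* — a small YAML document
assigning residue names to component classes, naming the head/tail atoms of
surfactant residues, and optionally overriding per-bead masses (coarse-grained
bead names carry no element, so masses cannot be guessed from them).

Internal units are Å and ns; MDAnalysis native units (Å and ps) and GRO's nm
are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .frames import COMPONENT_CLASSES, ParticleFrame, Trajectory

#: residue name used when writing each component class
CLASS_TO_RESNAME = {
    "fatty_acid": "FAT",
    "protein": "PRO",
    "lps": "LPS",
    "saccharide": "SAC",
    "water": "SOL",
    "ion": "ION",
}
HEAD_ATOM, TAIL_ATOM, BODY_ATOM = "HD", "TL", "BB"

#: fallback bead masses (amu) per class when a map gives no override
_CLASS_DEFAULT_MASS = {
    "fatty_acid": 125.0,
    "protein": 2750.0,
    "lps": 1250.0,
    "saccharide": 180.2,
    "water": 18.02,
    "ion": 35.0,
}


class ComponentMapError(ValueError):
    """Raised for unmapped residues or malformed component maps."""


@dataclass
class ComponentMap:
    """Residue-name bindings for third-party (or round-tripped) data.

    Attributes
    ----------
    classes : residue name -> component class.
    head_tail : residue name -> (head atom name, tail atom name) for
        surfactant residues.
    masses : residue name -> either a scalar bead mass or a
        {atom name: mass} mapping.
    """

    classes: dict[str, str]
    head_tail: dict[str, tuple[str, str]] = field(default_factory=dict)
    masses: dict[str, float | dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, cls in self.classes.items():
            if cls not in COMPONENT_CLASSES:
                raise ComponentMapError(f"residue {res!r} mapped to unknown class {cls!r}")

    @classmethod
    def default(cls) -> "ComponentMap":
        return cls(
            classes={v: k for k, v in CLASS_TO_RESNAME.items()},
            head_tail={"FAT": (HEAD_ATOM, TAIL_ATOM)},
            masses={},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComponentMap":
        raw = yaml.safe_load(Path(path).read_text())
        ht = {k: tuple(v) for k, v in (raw.get("head_tail") or {}).items()}
        return cls(classes=raw["classes"], head_tail=ht, masses=raw.get("masses") or {})

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "classes": dict(self.classes),
            "head_tail": {k: list(v) for k, v in self.head_tail.items()},
            "masses": self.masses,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def bead_mass(self, resname: str, atom_name: str) -> float:
        ov = self.masses.get(resname)
        if isinstance(ov, dict):
            if atom_name in ov:
                return float(ov[atom_name])
        elif ov is not None:
            return float(ov)
        return _CLASS_DEFAULT_MASS[self.classes[resname]]


def _universe_from_frame(frame: ParticleFrame):
    import MDAnalysis as mda

    mols, inverse = np.unique(frame.molecule_id, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=frame.n_beads,
        n_residues=len(mols),
        atom_resindex=inverse,
        trajectory=True,
    )
    resnames = np.empty(len(mols), dtype="U4")
    # a molecule's class is the class of its beads (uniform per molecule)
    first_bead = np.zeros(len(mols), dtype=np.int64)
    first_bead[inverse[::-1]] = np.arange(frame.n_beads - 1, -1, -1)
    for i, m in enumerate(mols):
        resnames[i] = CLASS_TO_RESNAME[str(frame.component_class[first_bead[i]])]
    names = np.full(frame.n_beads, BODY_ATOM, dtype="U4")
    names[frame.head_indices] = HEAD_ATOM
    names[frame.tail_indices] = TAIL_ATOM
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("masses", frame.masses)
    u.add_TopologyAttr("resids", np.arange(1, len(mols) + 1))
    u.atoms.positions = frame.coordinates  # MDAnalysis positions are Å
    u.dimensions = None
    return u


def write_system(
    frame_or_traj: ParticleFrame | Trajectory,
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
) -> None:
    """Write a frame (PDB/GRO/XYZ) and optionally a trajectory (DCD/XTC).

    The topology file holds the first frame; component classes are encoded as
    residue names (see :data:`CLASS_TO_RESNAME`) and surfactant head/tail
    beads as atom names HD/TL.
    """
    import MDAnalysis as mda

    if isinstance(frame_or_traj, Trajectory):
        traj = frame_or_traj
        frame = traj[0]
    else:
        traj = None
        frame = frame_or_traj
    u = _universe_from_frame(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            if traj is None:
                raise ValueError("trajectory output requested for a single frame")
            with mda.Writer(str(trajectory_path), n_atoms=frame.n_beads) as w:
                for i, f in enumerate(traj):
                    u.atoms.positions = f.coordinates
                    u.trajectory.ts.time = f.time * 1000.0  # ns -> ps
                    u.trajectory.ts.frame = i
                    w.write(u.atoms)


def read_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    component_map: ComponentMap | str | Path | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read coordinate/trajectory files into a :class:`Trajectory`.

    Parameters
    ----------
    component_map : a :class:`ComponentMap`, a YAML path, or None for the
        default map (which understands files written by :func:`write_system`).
    dt : frame spacing in ns; overrides file metadata when given (frame times
        then become ``frame_index * dt``).

    Raises
    ------
    ComponentMapError
        Listing every residue name present in the file but absent from the map.
    ValueError
        On an atom-count mismatch between topology and trajectory.
    """
    import MDAnalysis as mda

    if component_map is None:
        cmap = ComponentMap.default()
    elif isinstance(component_map, ComponentMap):
        cmap = component_map
    else:
        cmap = ComponentMap.from_yaml(component_map)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(trajectory_path))
        except ValueError as exc:
            msg = str(exc)
            if "number of atoms" in msg.lower() or "mismatch" in msg.lower():
                raise ValueError(f"topology/trajectory atom-count mismatch: {msg}") from exc
            raise

    resnames = u.atoms.resnames
    unmapped = sorted(set(resnames) - set(cmap.classes))
    if unmapped:
        raise ComponentMapError(f"unmapped residue names: {unmapped}")

    classes = np.array([cmap.classes[r] for r in resnames], dtype="U12")
    names = u.atoms.names if hasattr(u.atoms, "names") else np.full(len(u.atoms), BODY_ATOM)
    masses = np.array([cmap.bead_mass(r, n) for r, n in zip(resnames, names)])
    mol_ids = u.atoms.resindices.astype(np.int64)

    surf_ids, heads, tails = [], [], []
    for res in u.residues:
        if res.resname in cmap.head_tail:
            h_name, t_name = cmap.head_tail[res.resname]
            res_names = res.atoms.names
            h = np.flatnonzero(res_names == h_name)
            t = np.flatnonzero(res_names == t_name)
            if len(h) != 1 or len(t) != 1:
                raise ComponentMapError(
                    f"residue {res.resname} {res.resid}: head/tail atoms "
                    f"{h_name}/{t_name} do not resolve uniquely"
                )
            surf_ids.append(res.resindex)
            heads.append(int(res.atoms.indices[h[0]]))
            tails.append(int(res.atoms.indices[t[0]]))

    frames: list[ParticleFrame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            if dt is not None:
                t = i * dt
            else:
                t = (ts.time if np.isfinite(ts.time) else i) / 1000.0  # ps -> ns
            frames.append(
                ParticleFrame(
                    coordinates=u.atoms.positions.astype(np.float64).copy(),
                    masses=masses,
                    molecule_id=mol_ids,
                    component_class=classes,
                    surfactant_ids=np.array(surf_ids, dtype=np.int64),
                    head_indices=np.array(heads, dtype=np.int64),
                    tail_indices=np.array(tails, dtype=np.int64),
                    time=t,
                )
            )
    if len(frames) > 1:
        step = frames[1].time - frames[0].time
        if step <= 0:  # missing/zero time metadata: fall back to unit spacing
            step = dt if dt else 1.0
            for i, f in enumerate(frames):
                f.time = i * step
    else:
        step = dt if dt else 1.0
    box = None
    if u.dimensions is not None and np.any(u.dimensions[:3] > 0):
        box = float(u.dimensions[0])
    return Trajectory(frames=frames, dt=step, box_edge=box)
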