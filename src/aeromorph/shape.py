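"""Gyration-tensor shape descriptors.

The gyration tensor is the second moment of (optionally mass-weighted) bead
positions about their centroid,

    S_ab = sum_i w_i (r_ia - rbar_a)(r_ib - rbar_b) / sum_i w_i .

Its ordered eigenvalues l1 >= l2 >= l3 (Å²) yield two scalar descriptors:

* asphericity  phi = l1 - (l2 + l3)/2, zero for an isotropic (spherical)
  distribution and growing as the shape elongates; reported in Å².
* relative shape anisotropy  kappa² = 1 - 3(l1 l2 + l2 l3 + l3 l1)/(l1+l2+l3)²,
  dimensionless in [0, 1]: 0 for spherical/tetrahedral symmetry, 1 when all
  beads are collinear, and 1/4 for a planar isotropic (disc) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import ParticleFrame, Trajectory


@dataclass(frozen=True)
class ShapeMetrics:
    lambda1: float
    lambda2: float
    lambda3: float
    phi: float
    kappa2: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda1 >= self.lambda2 >= self.lambda3 >= -1e-9):
            raise ValueError("eigenvalues must be nonnegative and sorted descending")
        if not (-1e-12 <= self.kappa2 <= 1 + 1e-12):
            raise ValueError("kappa2 must lie in [0, 1]")


def gyration_tensor(frame: ParticleFrame, mass_weighted: bool = True) -> np.ndarray:
    """3x3 gyration tensor of a frame, Å².

    Mass weighting is the default; pass ``mass_weighted=False`` for the plain
    coordinate covariance (population normalization).
    """
    return gyration_tensor_points(
        frame.coordinates, frame.masses if mass_weighted else None
    )


def gyration_tensor_points(
    points: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Gyration tensor of raw points with optional weights."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("need at least 2 points of shape (N, 3)")
    if weights is None:
        w = np.ones(len(points))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive total")
    centred = points - (w @ points) / w.sum()
    return (centred.T * w) @ centred / w.sum()


def shape_metrics(S: np.ndarray, time: float = 0.0) -> ShapeMetrics:
    """Eigenvalues, asphericity and relative shape anisotropy of a tensor.

    Raises
    ------
    ValueError
        If ``S`` is not symmetric positive semidefinite, or is the zero
        tensor (kappa² is undefined for a single point).
    """
    S = np.asarray(S, dtype=np.float64)
    if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("S must be a symmetric 3x3 matrix")
    lam = np.linalg.eigvalsh(S)[::-1]
    if lam[2] < -1e-9 * max(1.0, lam[0]):
        raise ValueError("S must be positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    trace = lam.sum()
    if trace <= 0:
        raise ValueError("zero gyration tensor: shape descriptors undefined")
    phi = lam[0] - 0.5 * (lam[1] + lam[2])
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / trace**2
    # alternate closed form, used as an internal consistency guard
    kappa2_alt = 1.5 * (lam @ lam) / trace**2 - 0.5
    if abs(kappa2 - kappa2_alt) > 1e-12:
        raise AssertionError("kappa2 closed forms disagree beyond 1e-12")
    kappa2 = min(max(kappa2, 0.0), 1.0)
    return ShapeMetrics(float(lam[0]), float(lam[1]), float(lam[2]), float(phi), float(kappa2), time)


def shape_series(
    traj: Trajectory,
    selection: str | np.ndarray | None = None,
    mass_weighted: bool = True,
) -> list[ShapeMetrics]:
    """Per-frame shape metrics for a trajectory.

    ``selection`` may be a component class name, a boolean bead mask, or None
    for the whole particle (the default — the particle's shape includes its
    water).
    """
    out = []
    for i, frame in enumerate(traj):
        if selection is None:
            mask = slice(None)
        elif isinstance(selection, str):
            mask = frame.select(selection)
            if not mask.any():
                raise ValueError(f"selection {selection!r} empty in frame {i}")
        else:
            mask = np.asarray(selection, dtype=bool)
            if not mask.any():
                raise ValueError(f"selection empty in frame {i}")
        S = gyration_tensor_points(
            frame.coordinates[mask], frame.masses[mask] if mass_weighted else None
        )
        out.append(shape_metrics(S, time=frame.time))
    return out


def shape_table(metrics: list[ShapeMetrics]) -> pd.DataFrame:
    """Tidy table of a shape series (columns as written to CSV)."""
    return pd.DataFrame(
        {
            "time_ns": [m.time for m in metrics],
            "lambda1": [m.lambda1 for m in metrics],
            "lambda2": [m.lambda2 for m in metrics],
            "lambda3": [m.lambda3 for m in metrics],
            "phi_A2": [m.phi for m in metrics],
            "kappa2": [m.kappa2 for m in metrics],
        }
    )
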