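"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from aeromorph.frames import ParticleFrame, Trajectory


def uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * (radius * rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0))[:, None]


def water_frame(points: np.ndarray) -> ParticleFrame:
    """A frame of single-bead waters at the given positions."""
    n = len(points)
    return ParticleFrame(
        coordinates=points,
        masses=np.full(n, 18.02),
        molecule_id=np.arange(n),
        component_class=np.full(n, "water"),
    )


def lipid_frame(
    midpoints: np.ndarray,
    orientations: np.ndarray,
    rod_length: float = 10.0,
    water_points: np.ndarray | None = None,
) -> ParticleFrame:
    """2-bead fatty-acid rods centred on ``midpoints`` pointing head->tail
    along ``orientations``, with optional water filler beads."""
    midpoints = np.asarray(midpoints, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)
    n = len(midpoints)
    heads = midpoints - 0.5 * rod_length * orientations
    tails = midpoints + 0.5 * rod_length * orientations
    coords = np.stack([heads, tails], axis=1).reshape(-1, 3)
    masses = np.full(2 * n, 128.2)
    mol = np.repeat(np.arange(n), 2)
    cls = np.full(2 * n, "fatty_acid", dtype="U12")
    if water_points is not None:
        nw = len(water_points)
        coords = np.concatenate([coords, water_points])
        masses = np.concatenate([masses, np.full(nw, 18.02)])
        mol = np.concatenate([mol, np.arange(n, n + nw)])
        cls = np.concatenate([cls, np.full(nw, "water", dtype="U12")])
    return ParticleFrame(
        coordinates=coords,
        masses=masses,
        molecule_id=mol,
        component_class=cls,
        surfactant_ids=np.arange(n),
        head_indices=2 * np.arange(n),
        tail_indices=2 * np.arange(n) + 1,
    )


def static_trajectory(frame: ParticleFrame, n_frames: int, dt: float = 0.1) -> Trajectory:
    frames = [frame.with_coordinates(frame.coordinates.copy(), time=k * dt) for k in range(n_frames)]
    return Trajectory(frames=frames, dt=dt)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
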