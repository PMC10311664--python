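"""End-to-end orchestration: generate -> shape -> cluster -> partition ->
diffuse -> surface.

One YAML config (or :class:`PipelineConfig`) drives every stage; a single
seed is fanned out deterministically to the particle and trajectory
generators, so identical config + seed gives identical reports. Stages can be
selected individually; a failing stage aborts its dependents and the raised
:class:`StageError` lists what had completed.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as _cl
from . import surface as _surf
from .composition import build_composition
from .ellipsoid import (
    assign_regions,
    fit_bounding_ellipsoid,
    region_mass_fractions,
    shell_boundaries,
)
from .frames import Trajectory
from .generate import generate_brownian_trajectory, generate_particle
from .io import read_system
from .report import MorphologyReport, write_report
from .shape import shape_series, shape_table
from .transport import radial_diffusion_profile

log = logging.getLogger("aeromorph.pipeline")

ALL_STAGES = ("generate", "shape", "cluster", "partition", "diffuse", "surface")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed
        self.cause = cause


@dataclass
class PipelineConfig:
    # input: either a generator spec ...
    system: str = "A"
    diameter: float = 200.0
    seed: int = 0
    # ... or files
    topology: str | None = None
    trajectory: str | None = None
    component_map: str | None = None

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    # synthetic trajectory (Brownian water) parameters
    dt: float = 0.05
    n_frames: int = 50
    shell_D: list | None = None  # [[r_lo, r_hi, D], ...]; default single band

    # stage parameters
    eps: float = _cl.DEFAULT_EPS
    min_samples: int = _cl.DEFAULT_MIN_SAMPLES
    orientation_weight: float = _cl.DEFAULT_ORIENTATION_WEIGHT
    n_shells: int = 3
    n_slices: int = 5
    slice_length: float | None = None
    shell_edges: list | None = None
    a_lipid: float = _surf.DEFAULT_AREA_PER_LIPID
    d_exp: float = _surf.DEFAULT_D_EXP
    u_min: float = _cl.DEFAULT_U_MIN
    align_min: float = _cl.DEFAULT_ALIGN_MIN
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.eps <= 0 or self.min_samples < 1 or self.n_shells < 1:
            raise ConfigError("eps, min_samples and n_shells must be positive")
        if self.dt <= 0 or self.n_frames < 1:
            raise ConfigError("dt and n_frames must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) % 2**31)]


def run_pipeline(config: PipelineConfig) -> MorphologyReport:
    """Execute the requested stages in dependency order."""
    report = MorphologyReport(config=asdict(config))
    completed: list[str] = []
    stages = [s for s in ALL_STAGES if s in config.stages]

    traj: Trajectory | None = None
    seeds = _child_seeds(config.seed, 2)

    def run(stage: str, fn) -> None:
        nonlocal completed
        t0 = _time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise StageError(stage, completed, exc) from exc
        completed.append(stage)
        report.stages.append(stage)
        log.info("stage %-9s done in %.2f s", stage, _time.perf_counter() - t0)

    # --- input -----------------------------------------------------------
    def do_input() -> None:
        nonlocal traj
        if config.topology is not None:
            traj = read_system(config.topology, config.trajectory, config.component_map)
        else:
            comp, counts = build_composition(config.system, config.diameter)
            frame = generate_particle(comp, counts, seed=seeds[0])
            # default band extends past the nominal radius so that beads near
            # the rim (and the reflecting wall) stay covered
            bands = config.shell_D or [[0.0, 0.75 * config.diameter, 1.0]]
            shell_D = [((lo, hi), d) for lo, hi, d in bands]
            traj = generate_brownian_trajectory(
                frame, shell_D, dt=config.dt, n_frames=config.n_frames, seed=seeds[1]
            )

    if "generate" in stages or config.topology is None:
        run("generate", do_input)
    else:
        do_input()
    assert traj is not None

    last = traj[-1]
    ellipsoid = None
    assignments = None
    features = None

    if "shape" in stages:
        def do_shape() -> None:
            report.shape = shape_table(shape_series(traj))
        run("shape", do_shape)

    if "cluster" in stages:
        def do_cluster() -> None:
            nonlocal assignments, features
            params = _cl.ClusterParams(
                eps=config.eps,
                min_samples=config.min_samples,
                orientation_weight=config.orientation_weight,
            )
            assignments = _cl.clustering_kinetics(traj, params)
            features = _cl.lipid_features(last, w=config.orientation_weight)
            report.kinetics = pd.DataFrame(
                {
                    "time_ns": [a.time for a in assignments],
                    "fraction_clustered": [a.fraction_clustered for a in assignments],
                    "n_clusters": [a.n_clusters for a in assignments],
                }
            )
            report.cluster_labels = assignments[-1]
        run("cluster", do_cluster)

    if "partition" in stages:
        def do_partition() -> None:
            nonlocal ellipsoid
            ellipsoid = fit_bounding_ellipsoid(last)
            bounds = shell_boundaries(config.n_shells)
            labels = assign_regions(last, ellipsoid, bounds)
            report.ellipsoid = ellipsoid
            report.partition = region_mass_fractions(last, labels, bounds)
        run("partition", do_partition)

    if "diffuse" in stages:
        def do_diffuse() -> None:
            edges = config.shell_edges
            if edges is None:
                r = config.diameter / 2.0
                edges = [0.0, r / 2.0, r * 1.5]
            report.diffusion = radial_diffusion_profile(
                traj,
                edges,
                slice_length=config.slice_length,
                n_slices=config.n_slices,
            )
        run("diffuse", do_diffuse)

    if "surface" in stages:
        def do_surface() -> None:
            nonlocal ellipsoid
            if assignments is None or features is None:
                raise RuntimeError("surface stage requires the cluster stage")
            if ellipsoid is None:
                ellipsoid = fit_bounding_ellipsoid(last)
            rafts = _cl.identify_surface_rafts(
                assignments[-1], features, ellipsoid,
                u_min=config.u_min, align_min=config.align_min,
            )
            report.surface = _surf.build_surface_report(
                rafts, features, ellipsoid, assignments[-1].labels, a_lipid=config.a_lipid
            )
            report.exposure = _surf.residue_exposure(
                traj, traj[0].select("fatty_acid"), ellipsoid, d_exp=config.d_exp
            )
        run("surface", do_surface)

    if config.out_dir:
        write_report(report, config.out_dir)
    return report
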