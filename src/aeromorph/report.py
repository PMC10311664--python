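"""Deterministic serialization of analysis results.

A :class:`MorphologyReport` gathers whichever stages a run produced. Tabular
sections go to CSV, scalar/structured sections to one ``report.json`` with a
schema version; empty sections are simply omitted so that the same layout
serves partial runs. Serialization is deterministic: identical reports give
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .ellipsoid import EllipsoidModel, ShellPartition
from .surface import ExposureMap, SurfaceReport
from .transport import DiffusionFit, DiffusionProfile

SCHEMA_VERSION = "1"


@dataclass
class MorphologyReport:
    config: dict | None = None
    shape: pd.DataFrame | None = None
    kinetics: pd.DataFrame | None = None
    ellipsoid: EllipsoidModel | None = None
    partition: ShellPartition | None = None
    diffusion: DiffusionProfile | None = None
    surface: SurfaceReport | None = None
    exposure: ExposureMap | None = None
    cluster_labels: ClusterAssignment | None = None
    schema_version: str = SCHEMA_VERSION
    stages: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        """JSON-serializable view of the non-tabular sections."""
        out: dict = {"schema_version": self.schema_version, "stages": sorted(self.stages)}
        if self.config is not None:
            out["config"] = self.config
        if self.ellipsoid is not None:
            out["ellipsoid"] = {
                "center": self.ellipsoid.center.tolist(),
                "semi_axes": self.ellipsoid.semi_axes.tolist(),
                "rotation": self.ellipsoid.rotation.tolist(),
                "volume_A3": self.ellipsoid.volume,
                "surface_area_A2": self.ellipsoid.surface_area(),
            }
        if self.diffusion is not None:
            out["diffusion"] = _diffusion_dict(self.diffusion)
        if self.surface is not None:
            s = self.surface
            out["surface"] = {
                "A_surface_A2": s.A_surface,
                "a_lipid_A2": s.a_lipid,
                "n_sites": s.n_sites,
                "n_total_fa": s.n_total_fa,
                "n_surface_fa": s.n_surface_fa,
                "coverage_percent": s.coverage_percent,
                "excess_predicted": s.excess_predicted,
                "excess_measured": s.excess_measured,
                "raft_sizes": {str(k): v for k, v in sorted(s.raft_sizes.items())},
                "raft_curvatures_per_A": {
                    str(k): v for k, v in sorted(s.raft_curvatures.items())
                },
                "weighted_mean_curvature_per_A": s.weighted_mean_curvature,
            }
        return out


def _fit_dict(fit: DiffusionFit | None) -> dict | None:
    if fit is None:
        return None
    return {
        "D_A2_per_ns": fit.D,
        "D_cm2_per_s": fit.D_cm2_per_s,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "stderr": fit.stderr,
    }


def _diffusion_dict(prof: DiffusionProfile) -> dict:
    return {
        "shell_edges_A": np.asarray(prof.shell_edges).tolist(),
        "D_global": _fit_dict(prof.D_global),
        "D_per_shell": [_fit_dict(f) for f in prof.D_per_shell],
        "mean_counts_per_shell": np.asarray(prof.counts).tolist(),
    }


def write_report(report: MorphologyReport, out_dir: str | Path) -> list[Path]:
    """Write a report to ``out_dir``; returns the files written.

    Raises
    ------
    OSError
        If the output directory cannot be created or written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out / "report.json"
    path.write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n")
    written.append(path)

    if report.shape is not None:
        p = out / "shape.csv"
        report.shape.to_csv(p, index=False)
        written.append(p)
    if report.kinetics is not None:
        p = out / "kinetics.csv"
        report.kinetics.to_csv(p, index=False)
        written.append(p)
    if report.partition is not None:
        p = out / "partition.csv"
        report.partition.table.to_csv(p)
        written.append(p)
    if report.diffusion is not None and report.diffusion.msd_global is not None:
        msd = report.diffusion.msd_global
        df = pd.DataFrame({"tau_ns": msd.tau, "msd_A2": msd.mean})
        for s in range(msd.per_slice.shape[0]):
            df[f"msd_slice{s}_A2"] = msd.per_slice[s]
        p = out / "msd.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if report.exposure is not None:
        p = out / "exposure.csv"
        pd.DataFrame(
            {
                "molecule_id": report.exposure.molecule_ids,
                "exposure_frequency": report.exposure.frequency,
            }
        ).to_csv(p, index=False)
        written.append(p)
    if report.cluster_labels is not None:
        p = out / "cluster_labels.csv"
        pd.DataFrame({"label": report.cluster_labels.labels}).to_csv(p, index_label="lipid_index")
        written.append(p)
    return written


def read_report_json(path: str | Path) -> dict:
    """Load a written ``report.json`` back into a dict."""
    return json.loads(Path(path).read_text())
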