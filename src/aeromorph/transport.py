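"""Mean-squared displacement and water diffusion coefficients.

The trajectory tail is cut into consecutive time slices (by default the
analysis mirrors the "several ~10 ns slices" style of averaging: each slice
contributes one MSD curve with its first frame as the single time origin, and
curves are averaged across slices). The diffusion coefficient follows from
the Einstein relation in three dimensions, MSD(tau) = 6 D tau, as the OLS
slope over a fit window that skips the short-time region; the intercept is
reported, not constrained.

A radial profile repeats the same estimate for waters grouped into spherical
shells around the particle centre, with shell membership frozen at each
slice start so that beads crossing shells mid-slice do not mix estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import Trajectory

#: 1 Å²/ns in cm²/s
A2_PER_NS_TO_CM2_PER_S = 1e-5


@dataclass
class MSDResult:
    """MSD curves from slice-origin averaging."""

    tau: np.ndarray  # lag times, ns (starts at 0)
    per_slice: np.ndarray  # (n_slices, n_lags)
    mean: np.ndarray  # (n_lags,)
    n_beads: int


@dataclass
class DiffusionFit:
    D: float  # Å²/ns
    slope: float
    intercept: float
    r_squared: float
    stderr: float  # standard error of the slope

    @property
    def D_cm2_per_s(self) -> float:
        return self.D * A2_PER_NS_TO_CM2_PER_S


@dataclass
class DiffusionProfile:
    shell_edges: np.ndarray
    D_per_shell: list[DiffusionFit | None]
    counts: np.ndarray  # mean bead count per shell over slices
    D_global: DiffusionFit | None = None
    msd_global: MSDResult | None = None
    msd_per_shell: list[MSDResult | None] = field(default_factory=list)


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    frame0 = traj[0]
    if selection is None:
        selection = "water"
    if isinstance(selection, str):
        mask = frame0.select(selection)
    else:
        mask = np.asarray(selection, dtype=bool)
    if not mask.any():
        raise ValueError("selection is empty")
    return mask


def _slice_starts(n_frames: int, frames_per_slice: int, n_slices: int) -> list[int]:
    needed = frames_per_slice * n_slices
    if needed > n_frames:
        raise ValueError(
            f"trajectory too short: {n_frames} frames < {n_slices} slices x "
            f"{frames_per_slice} frames"
        )
    first = n_frames - needed  # use the trajectory tail
    return [first + k * frames_per_slice for k in range(n_slices)]


def compute_msd(
    traj: Trajectory,
    selection=None,
    slice_length: float | None = None,
    n_slices: int = 5,
    multi_origin: bool = False,
) -> MSDResult:
    """MSD(tau) averaged over beads and slices.

    ``slice_length`` is in ns; by default the tail of the trajectory is split
    into ``n_slices`` equal slices. With ``multi_origin=True`` every frame of
    a slice serves as a time origin (more averaging, correlated samples);
    the default uses only the slice start, so slices are independent.
    """
    mask = _resolve_selection(traj, selection)
    pos = traj.positions(mask)
    n_frames = len(traj)
    if slice_length is None:
        fps = n_frames // n_slices
    else:
        fps = int(round(slice_length / traj.dt))
    if fps < 2:
        raise ValueError("slice must span at least 2 frames")
    starts = _slice_starts(n_frames, fps, n_slices)

    curves = np.empty((n_slices, fps))
    for s, start in enumerate(starts):
        window = pos[start : start + fps]
        if multi_origin:
            acc = np.zeros(fps)
            cnt = np.zeros(fps)
            for o in range(fps):
                disp = window[o:] - window[o]
                sq = np.einsum("tij,tij->t", disp, disp) / disp.shape[1]
                acc[: fps - o] += sq
                cnt[: fps - o] += 1
            curves[s] = acc / cnt
        else:
            disp = window - window[0]
            curves[s] = np.einsum("tij,tij->t", disp, disp) / disp.shape[1]
    tau = np.arange(fps) * traj.dt
    return MSDResult(tau=tau, per_slice=curves, mean=curves.mean(axis=0), n_beads=int(mask.sum()))


def fit_diffusion_coefficient(
    msd: np.ndarray,
    tau: np.ndarray,
    fit_window: tuple[float, float] | None = None,
) -> DiffusionFit:
    """Einstein-relation fit D = slope/6 over ``fit_window`` (ns).

    The default window spans 10-80% of the curve's duration, skipping the
    short-time region where slice-origin statistics are noisiest.
    """
    tau = np.asarray(tau, dtype=np.float64)
    msd = np.asarray(msd, dtype=np.float64)
    defaulted = fit_window is None
    if defaulted:
        fit_window = (0.1 * tau[-1], 0.8 * tau[-1])
    lo, hi = fit_window
    sel = (tau >= lo) & (tau <= hi)
    if sel.sum() < 2:
        if defaulted:  # very short curves: fall back to the whole curve
            sel = np.ones_like(tau, dtype=bool)
        else:
            raise ValueError(f"fit window {fit_window} contains fewer than 2 points")
    x, y = tau[sel], msd[sel]
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    stderr = np.sqrt(ss_res / max(n - 2, 1) / sxx)
    return DiffusionFit(
        D=slope / 6.0, slope=float(slope), intercept=float(intercept),
        r_squared=r2, stderr=float(stderr),
    )


def radial_diffusion_profile(
    traj: Trajectory,
    shell_edges,
    selection=None,
    slice_length: float | None = None,
    n_slices: int = 5,
    fit_window: tuple[float, float] | None = None,
    center: np.ndarray | None = None,
) -> DiffusionProfile:
    """Per-shell water diffusion coefficients.

    ``shell_edges`` are radii in Å (e.g. ``[0, 100, 150, 200]`` for three
    shells). Waters are binned by their distance from the particle centre at
    each slice start and keep that membership for the slice. A shell that is
    empty in every slice yields ``None`` (a missing value, not zero), and the
    set of empty shells is reported in the raised error only when *all*
    selected waters fall outside the outermost edge.
    """
    edges = np.asarray(shell_edges, dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("shell_edges must be increasing with at least 2 entries")
    mask = _resolve_selection(traj, selection)
    pos = traj.positions(mask)
    n_frames = len(traj)
    if slice_length is None:
        fps = n_frames // n_slices
    else:
        fps = int(round(slice_length / traj.dt))
    if fps < 2:
        raise ValueError("slice must span at least 2 frames")
    starts = _slice_starts(n_frames, fps, n_slices)
    n_shells = len(edges) - 1

    # global curve and fit
    msd_global = compute_msd(traj, selection=mask, slice_length=slice_length, n_slices=n_slices)
    d_global = fit_diffusion_coefficient(msd_global.mean, msd_global.tau, fit_window)

    shell_curves: list[list[np.ndarray]] = [[] for _ in range(n_shells)]
    shell_counts = np.zeros((n_slices, n_shells))
    any_inside = False
    for s, start in enumerate(starts):
        window = pos[start : start + fps]
        if center is None:
            frame = traj[start]
            c = frame.centroid()
        else:
            c = np.asarray(center, dtype=np.float64)
        radii = np.linalg.norm(window[0] - c, axis=1)
        bins = np.digitize(radii, edges) - 1  # shell index; out of range -> -1 or n_shells
        for k in range(n_shells):
            members = bins == k
            shell_counts[s, k] = members.sum()
            if members.sum() == 0:
                continue
            any_inside = True
            disp = window[:, members] - window[0, members]
            shell_curves[k].append(np.einsum("tij,tij->t", disp, disp) / members.sum())
    if not any_inside:
        raise ValueError(
            f"all selected beads fall outside the shells (empty shells: {list(range(n_shells))})"
        )

    tau = np.arange(fps) * traj.dt
    fits: list[DiffusionFit | None] = []
    msds: list[MSDResult | None] = []
    for k in range(n_shells):
        if not shell_curves[k]:
            fits.append(None)
            msds.append(None)
            continue
        per_slice = np.stack(shell_curves[k])
        res = MSDResult(tau=tau, per_slice=per_slice, mean=per_slice.mean(axis=0),
                        n_beads=int(shell_counts[:, k].max()))
        msds.append(res)
        fits.append(fit_diffusion_coefficient(res.mean, tau, fit_window))
    return DiffusionProfile(
        shell_edges=edges,
        D_per_shell=fits,
        counts=shell_counts.mean(axis=0),
        D_global=d_global,
        msd_global=msd_global,
        msd_per_shell=msds,
    )
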