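"""Bounding-ellipsoid fitting and equal-volume concentric-shell partitioning.

The particle body is approximated by the minimum-volume enclosing ellipsoid
(MVEE) of its convex hull vertices, computed with Khachiyan's algorithm. The
fitted ellipsoid defines a dimensionless ellipsoidal coordinate

    u(p) = | diag(1/a, 1/b, 1/c) . R^T . (p - center) |

which is 0 at the centre and 1 on the surface. Concentric similar ellipsoids
scaled by s_k = (k/N)^(1/3) split the body into N shells of exactly equal
volume; with N = 3 the shells are named core, bulk and surface, and per-class
mass percentages across the three regions summarize where each component
lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .frames import ORGANIC_CLASSES, ParticleFrame

REGION_NAMES_3 = ("core", "bulk", "surface")


@dataclass(frozen=True)
class EllipsoidModel:
    """A fitted ellipsoid: centre, sorted semi-axes and orientation.

    ``rotation`` columns are the principal directions; column j corresponds to
    semi-axis j (a >= b >= c).
    """

    center: np.ndarray
    semi_axes: np.ndarray  # (a, b, c), descending, Å
    rotation: np.ndarray  # 3x3 orthonormal

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=np.float64))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    def u(self, points: np.ndarray) -> np.ndarray:
        """Ellipsoidal coordinate of points (0 at centre, 1 on the surface)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        local = (points - self.center) @ self.rotation
        return np.linalg.norm(local / self.semi_axes, axis=1)

    def outward_normal(self, points: np.ndarray) -> np.ndarray:
        """Unit outward surface normal direction associated with each point.

        This is the gradient direction of u², evaluated at the point's radial
        footprint; undefined at the exact centre.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        local = (points - self.center) @ self.rotation
        if np.any(np.linalg.norm(local, axis=1) == 0):
            raise ValueError("normal undefined at the ellipsoid centre")
        grad = (local / self.semi_axes**2) @ self.rotation.T
        return grad / np.linalg.norm(grad, axis=1, keepdims=True)

    def surface_points(self, points: np.ndarray) -> np.ndarray:
        """Radial projection of points onto the ellipsoid surface."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        uu = self.u(points)
        if np.any(uu == 0):
            raise ValueError("cannot project the centre to the surface")
        return self.center + (points - self.center) / uu[:, None]

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    def surface_area(self, p: float = 1.6075) -> float:
        """Thomsen's approximation to the ellipsoid surface area, Å²."""
        a, b, c = self.semi_axes
        return float(4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p))

    def mean_curvature(self, points: np.ndarray) -> np.ndarray:
        """Mean curvature H (Å⁻¹) at each point's radial surface footpoint.

        Uses the closed form for the implicit surface F = sum (x_i/a_i)² - 1:
        H = (|∇F|² tr(Hess F) - ∇F·Hess F·∇F) / (2 |∇F|³), positive for a
        convex body (sphere of radius R gives 1/R everywhere).
        """
        foot = self.surface_points(points)
        local = (foot - self.center) @ self.rotation
        inv2 = 1.0 / self.semi_axes**2
        grad = 2.0 * local * inv2  # ∇F in principal frame
        g2 = np.einsum("ij,ij->i", grad, grad)
        tr_h = 2.0 * inv2.sum()
        ghg = np.einsum("ij,j,ij->i", grad, 2.0 * inv2, grad)
        return (g2 * tr_h - ghg) / (2.0 * g2**1.5)


def mvee(points: np.ndarray, tolerance: float = 1e-3, max_iter: int = 100_000) -> EllipsoidModel:
    """Minimum-volume enclosing ellipsoid by Khachiyan's barycentric ascent.

    Iterates the weight update until the maximum Mahalanobis-type residual is
    within ``(1 + tolerance) * d`` of the dimension, which bounds the relative
    volume excess; all input points then satisfy u <= 1 + O(tolerance).
    """
    P = np.asarray(points, dtype=np.float64)
    n, d = P.shape
    if n < d + 1:
        raise ValueError("need at least d+1 points")
    Q = np.column_stack([P, np.ones(n)])
    u_w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q.T @ (Q * u_w[:, None])
        M = np.einsum("ij,ji->i", Q, np.linalg.solve(X, Q.T))
        j = int(np.argmax(M))
        maximum = M[j]
        if maximum <= (d + 1) * (1.0 + tolerance):
            break
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        u_w *= 1.0 - step
        u_w[j] += step
    center = u_w @ P
    cov = P.T @ (P * u_w[:, None]) - np.outer(center, center)
    A = np.linalg.inv(cov) / d  # ellipsoid matrix: (x-c)^T A (x-c) <= 1
    evals, evecs = np.linalg.eigh(A)
    semi = 1.0 / np.sqrt(evals)  # ascending evals -> descending axes
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, -1] *= -1.0
    return EllipsoidModel(center=center, semi_axes=semi, rotation=evecs)


def fit_bounding_ellipsoid(
    frame: ParticleFrame,
    tolerance: float = 1e-3,
    *,
    selection: np.ndarray | None = None,
    exclude_vapor: bool = False,
) -> EllipsoidModel:
    """MVEE of a frame's convex hull vertices.

    ``exclude_vapor`` drops stray beads whose distance from the coordinate
    median exceeds 1.5x the 90th-percentile radius before fitting, so that a
    few evaporated waters do not inflate the hull. The cutoff is robust: it
    is derived from the bulk of the points, not from the strays themselves.

    Raises
    ------
    ValueError
        For degenerate (coplanar or collinear) input.
    """
    pts = frame.coordinates if selection is None else frame.coordinates[selection]
    if len(pts) < 4:
        raise ValueError("need at least 4 points to fit an ellipsoid")
    if exclude_vapor:
        radii = np.linalg.norm(pts - np.median(pts, axis=0), axis=1)
        keep = radii <= 1.5 * np.percentile(radii, 90)
        if keep.sum() >= 4:
            pts = pts[keep]
    return _fit_points(pts, tolerance)


def _fit_points(pts: np.ndarray, tolerance: float) -> EllipsoidModel:
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises on flat input
        raise ValueError(f"degenerate point set (coplanar or collinear): {exc}") from exc
    return mvee(pts[hull.vertices], tolerance=tolerance)


def shell_boundaries(n_shells: int = 3) -> np.ndarray:
    """Scale factors s_k = (k/N)^(1/3) bounding N equal-volume shells."""
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    return ((np.arange(1, n_shells + 1)) / n_shells) ** (1.0 / 3.0)


def assign_regions(
    frame: ParticleFrame,
    ellipsoid: EllipsoidModel,
    boundaries: np.ndarray | None = None,
) -> np.ndarray:
    """Shell index per bead (0 = innermost). Beads with u > 1 go outermost."""
    if boundaries is None:
        boundaries = shell_boundaries(3)
    boundaries = np.asarray(boundaries, dtype=np.float64)
    uu = ellipsoid.u(frame.coordinates)
    labels = np.searchsorted(boundaries, uu, side="left")
    return np.minimum(labels, len(boundaries) - 1)


@dataclass
class ShellPartition:
    """Per-region, per-component mass percentages."""

    n_shells: int
    boundaries: np.ndarray
    region_names: tuple[str, ...]
    table: pd.DataFrame = field(repr=False)

    def row(self, component: str) -> np.ndarray:
        return self.table.loc[component].to_numpy()


def region_mass_fractions(
    frame: ParticleFrame,
    labels: np.ndarray,
    boundaries: np.ndarray | None = None,
) -> ShellPartition:
    """Mass percentage of each component class across the shell regions.

    Rows sum to 100% per class; classes absent from the frame are omitted.
    An aggregate "organic" row (fatty acid + protein + LPS + saccharide) is
    appended, matching the way whole-particle mass distributions are usually
    reported.
    """
    if boundaries is None:
        boundaries = shell_boundaries(3)
    n_shells = len(boundaries)
    names = REGION_NAMES_3 if n_shells == 3 else tuple(f"shell_{k}" for k in range(n_shells))

    df = pd.DataFrame(
        {"cls": frame.component_class, "region": labels, "mass": frame.masses}
    )
    rows: dict[str, np.ndarray] = {}
    for cls, grp in df.groupby("cls", sort=True):
        total = grp["mass"].sum()
        by_region = grp.groupby("region")["mass"].sum().reindex(range(n_shells), fill_value=0.0)
        rows[str(cls)] = 100.0 * by_region.to_numpy() / total
    organic = df[df["cls"].isin(ORGANIC_CLASSES)]
    if len(organic):
        by_region = (
            organic.groupby("region")["mass"].sum().reindex(range(n_shells), fill_value=0.0)
        )
        rows["organic"] = 100.0 * by_region.to_numpy() / organic["mass"].sum()
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    table.index.name = "component"
    return ShellPartition(
        n_shells=n_shells,
        boundaries=np.asarray(boundaries, dtype=np.float64),
        region_names=names,
        table=table,
    )
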