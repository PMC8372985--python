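"""Least-squares sphere fitting with normal filtering and distance pruning.

The implant contact sphere (ILSS) is fitted to points picked on the
internal aspect of the middle deltoid.  The fit alternates three steps,
automating the software's interactive loop:

1. algebraic least squares (linear in center and r^2) followed by
   geometric refinement of sum(||p - c|| - r)^2;
2. elimination of points whose normals are inconsistent with the
   configured orientation convention relative to dir(point - center);
3. pruning of the fraction of points with the largest
   dist^2 = |  ||p - c||^2 - r^2 |.

The same machinery fits the acromial reference sphere (optionally with
pruning disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import least_squares

from .types import FitError, OrientedPointCloud, Sphere


@dataclass(frozen=True)
class FitConfig:
    prune_fraction: float = 0.10
    max_iterations: int = 5
    radius_tol: float = 0.05  # mm
    normal_sign: str = "inward"  # normals point toward the center

    def __post_init__(self):
        if not (0 <= self.prune_fraction < 1):
            raise ValueError("prune_fraction must be in [0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.normal_sign not in ("inward", "outward"):
            raise ValueError("normal_sign must be 'inward' or 'outward'")


@dataclass
class FitDiagnostics:
    radii: list[float] = field(default_factory=list)
    point_counts: list[int] = field(default_factory=list)
    eliminated_by_normal: list[int] = field(default_factory=list)
    converged: bool = False


def _algebraic_sphere(points: np.ndarray) -> Sphere:
    """Linearized fit: ||p||^2 = 2 p.c + (r^2 - ||c||^2)."""
    A = np.column_stack([2 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, residuals, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise FitError(
            "degenerate point configuration (coplanar or concentrated): "
            "a sphere cannot be determined"
        )
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise FitError("algebraic fit produced a non-positive radius")
    return Sphere(cent=c, r=math.sqrt(r2))


def fit_sphere_lsq(cloud: OrientedPointCloud) -> Sphere:
    """Least-squares sphere through a point cloud.

    Algebraic solve followed by geometric (orthogonal-distance)
    refinement of sum(||p - c|| - r)^2.  Exact on noiseless spherical
    data; raises FitError for < 4 points or degenerate configurations.
    """
    pts = cloud.points
    if len(pts) < 4:
        raise FitError(f"need at least 4 points to fit a sphere, got {len(pts)}")
    init = _algebraic_sphere(pts)

    def residual(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    x0 = np.array([*init.cent, init.r])
    res = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    c, r = res.x[:3], float(res.x[3])
    if r <= 0:
        raise FitError("geometric refinement produced a non-positive radius")
    return Sphere(cent=c, r=r)


def filter_by_normal(
    cloud: OrientedPointCloud, sphere: Sphere, config: FitConfig = FitConfig()
) -> OrientedPointCloud:
    """Drop points whose normals contradict the orientation convention.

    With the 'inward' convention (internal-aspect normals point toward
    the implant center), a point is eliminated when the scalar product
    normal . dir(point - center) is over 0.
    """
    d = cloud.points - sphere.cent
    dots = (cloud.normals * d).sum(axis=1)
    keep = dots <= 0 if config.normal_sign == "inward" else dots >= 0
    if not keep.any():
        raise FitError(
            "all points eliminated by the normal filter: the cloud's normal "
            f"orientation is inconsistent with the '{config.normal_sign}' convention"
        )
    return cloud.subset(keep)


def prune_farthest(
    cloud: OrientedPointCloud, sphere: Sphere, fraction: float
) -> OrientedPointCloud:
    """Remove ceil(fraction * N) points with the largest
    dist^2 = |  ||p - c||^2 - r^2 |; ties broken by original index
    (earlier points retained first)."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if len(cloud) == 0:
        raise FitError("cannot prune an empty cloud")
    if fraction == 0:
        return cloud
    d2 = np.abs(((cloud.points - sphere.cent) ** 2).sum(axis=1) - sphere.r**2)
    k = math.ceil(fraction * len(cloud))
    # Stable order: among equal distances, later-index points are removed.
    order = np.lexsort((-np.arange(len(cloud)), d2))
    keep = np.sort(order[: len(cloud) - k])
    return cloud.subset(keep)


def iterate_fit(
    cloud: OrientedPointCloud, config: FitConfig = FitConfig()
) -> tuple[Sphere, FitDiagnostics]:
    """Automated fit / normal-filter / prune loop.

    Stops when the radius change drops below ``radius_tol`` or after
    ``max_iterations``.  Raises FitError when fewer than 4 points remain.
    """
    diag = FitDiagnostics()
    current = cloud
    sphere = fit_sphere_lsq(current)
    diag.radii.append(sphere.r)
    diag.point_counts.append(len(current))

    for _ in range(config.max_iterations):
        n_before = len(current)
        current = filter_by_normal(current, sphere, config)
        diag.eliminated_by_normal.append(n_before - len(current))
        if config.prune_fraction > 0:
            current = prune_farthest(current, sphere, config.prune_fraction)
        if len(current) < 4:
            raise FitError(
                f"fewer than 4 points remain after filtering ({len(current)})"
            )
        new_sphere = fit_sphere_lsq(current)
        diag.radii.append(new_sphere.r)
        diag.point_counts.append(len(current))
        dr = abs(new_sphere.r - sphere.r)
        sphere = new_sphere
        if dr < config.radius_tol:
            diag.converged = True
            break
    return sphere, diag
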