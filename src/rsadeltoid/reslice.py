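"""Anatomical plane slices through a labeled shoulder volume.

Each slice plane is defined by three landmarks: the acromial reference
sphere center (Point 1), an insertion site on the acromial arc
(Point 2, stepping in 10 degree increments, with the four Sakoma bands
A2/A3/M1/P1 defining slices S4/S3/S2/S1), and the center of the humeral
diaphysis (Point 3).  The labeled volume is resampled into the plane
with a cubic falloff kernel, and the implant sphere is intersected with
the plane to give the in-plane pulley circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import GeometryError, InsertionSite, Sphere, LabeledVolume

# Sakoma insertion bands in arc order (posterior to anterior).
SITE_ORDER = ("P1", "M1", "A3", "A2")


@dataclass(frozen=True)
class AcromialArc:
    """Parametric arc along the lateral acromion carrying the deltoid's
    proximal insertion sites.

    A point at arc angle theta (degrees) lies on the acromial sphere:
    center + radius * (cos(elev) cos(theta) x + sin(elev) y + cos(elev) sin(theta) z),
    with theta = 0 facing lateral (+x) and positive theta anterior (+z).
    """

    center: np.ndarray  # acromial sphere center, mm
    radius: float  # acromial sphere radius, mm
    start_deg: float  # first arc angle
    span_deg: float  # total angular extent
    elevation_deg: float = 0.0  # elevation of the arc off the x-z plane

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("arc radius must be positive")
        if self.span_deg <= 0:
            raise ValueError("arc span must be positive")

    def point_at(self, theta_deg) -> np.ndarray:
        th = np.radians(np.asarray(theta_deg, dtype=float))
        el = math.radians(self.elevation_deg)
        d = np.stack(
            [
                math.cos(el) * np.cos(th),
                math.sin(el) * np.ones_like(th),
                math.cos(el) * np.sin(th),
            ],
            axis=-1,
        )
        return self.center + self.radius * d


def arc_candidates(arc: AcromialArc, step_degrees: float = 10.0) -> np.ndarray:
    """Candidate Point-2 positions every ``step_degrees`` along the arc
    (inclusive of both ends): a 180 degree arc at step 10 gives 19."""
    if step_degrees <= 0:
        raise GeometryError("arc step must be strictly positive degrees")
    n = int(round(arc.span_deg / step_degrees))
    if abs(n * step_degrees - arc.span_deg) > 1e-9:
        n = int(math.floor(arc.span_deg / step_degrees))
    thetas = arc.start_deg + step_degrees * np.arange(n + 1)
    return arc.point_at(thetas)


def insertion_points(
    arc: AcromialArc,
    step_degrees: float = 10.0,
    site_indices: tuple[int, int, int, int] = (0, 3, 9, 15),
) -> list[InsertionSite]:
    """The four Sakoma insertion sites, selected by arc index among the
    candidate positions, labeled P1 -> M1 -> A3 -> A2 in arc order."""
    if arc.span_deg < 30:
        raise GeometryError("acromial arc must span at least 30 degrees")
    candidates = arc_candidates(arc, step_degrees)
    if len(site_indices) != 4 or len(set(site_indices)) != 4:
        raise GeometryError("exactly four distinct arc indices are required")
    idx = sorted(int(i) for i in site_indices)
    if idx[-1] >= len(candidates) or idx[0] < 0:
        raise GeometryError(
            f"arc too short: index {idx[-1]} outside {len(candidates)} candidates"
        )
    return [
        InsertionSite(label=lab, position=candidates[i], arc_index=i)
        for lab, i in zip(SITE_ORDER, idx)
    ]


@dataclass(frozen=True)
class PlaneFrame:
    """Rigid frame of a slice plane.

    ``basis`` rows are the in-plane x, in-plane y and the plane normal
    (orthonormal, right-handed).  ``origin`` is the world position of
    plane coordinate (0, 0).  ``matrix`` maps homogeneous pixel
    coordinates (i, j, 0, 1) of the resampled image to world mm.
    """

    origin: np.ndarray  # (3,)
    basis: np.ndarray  # (3, 3): rows x_hat, y_hat, n_hat
    pixel_spacing: float = 0.5
    extent: float = 160.0

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=float))
        b = self.basis
        if not np.allclose(b @ b.T, np.eye(3), atol=1e-9):
            raise GeometryError("plane basis is not orthonormal")
        if np.linalg.det(b) < 0:
            raise GeometryError("plane basis is not right-handed")

    @property
    def x_hat(self) -> np.ndarray:
        return self.basis[0]

    @property
    def y_hat(self) -> np.ndarray:
        return self.basis[1]

    @property
    def normal(self) -> np.ndarray:
        return self.basis[2]

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent / self.pixel_spacing)) + 1

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous transform, pixel (i, j) -> world mm."""
        m = np.eye(4)
        m[:3, 0] = self.x_hat * self.pixel_spacing
        m[:3, 1] = self.y_hat * self.pixel_spacing
        m[:3, 2] = self.normal
        m[:3, 3] = self.plane_to_world(np.array([[-self.extent / 2, -self.extent / 2]]))[0]
        return m

    def world_to_plane(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return pts @ np.column_stack([self.x_hat, self.y_hat])

    def plane_to_world(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return self.origin + uv[:, :1] * self.x_hat + uv[:, 1:2] * self.y_hat

    def pixel_to_plane(self, ij: np.ndarray) -> np.ndarray:
        ij = np.atleast_2d(np.asarray(ij, dtype=float))
        return ij * self.pixel_spacing - self.extent / 2

    def plane_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return pts @ self.normal


@dataclass
class PlanarSlice:
    """A resampled 2D slice: label image, intensity image, frame, and
    the in-plane pulley circle from the sphere/plane intersection."""

    image: np.ndarray  # (n, n) integer labels
    intensity: np.ndarray  # (n, n) float, kernel-weighted label mass blend
    frame: PlaneFrame
    circle: tuple[np.ndarray, float] | None = None
    slice_label: str = ""

    def pixel_to_plane(self, ij: np.ndarray) -> np.ndarray:
        return self.frame.pixel_to_plane(ij)


def plane_from_three_points(
    p1,
    p2,
    p3,
    axis_direction=(0.0, 1.0, 0.0),
    pixel_spacing: float = 0.5,
    extent: float = 160.0,
) -> PlaneFrame:
    """Slice plane through Point 1 (acromial sphere center), Point 2
    (insertion site) and Point 3 (diaphysis center).

    The in-plane y axis is the projection of the humeral diaphysis
    direction into the plane (so the slice y axis is the Y'Y axis of the
    force model); the origin is Point 3.  The in-plane x axis is oriented
    so world-lateral (+X) maps to +x.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p1 - p3, p2 - p3)
    nn = np.linalg.norm(n)
    if nn < 1e-12 * max(np.linalg.norm(p1 - p3), np.linalg.norm(p2 - p3), 1.0):
        raise GeometryError("the three plane-defining points are collinear")
    n = n / nn
    axis = np.asarray(axis_direction, dtype=float)
    y = axis - (axis @ n) * n
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise GeometryError("diaphysis axis is perpendicular to the slice plane")
    y = y / ny
    if y @ axis < 0:
        y = -y
    x = np.cross(y, n)
    if x @ np.array([1.0, 0.0, 0.0]) < 0:
        n, x = -n, -x
    basis = np.vstack([x, y, n])
    return PlaneFrame(origin=p3, basis=basis, pixel_spacing=pixel_spacing, extent=extent)


def cubic_weight(t: np.ndarray) -> np.ndarray:
    """Falloff kernel w(t) = 2t^3 - 3t^2 + 1 on t in [0, 1] (clamped).

    w(0) = 1, w(1) = 0, and w(t) + w(1 - t) = 1, so per-axis products
    over the 8 cell corners form a partition of unity.
    """
    t = np.clip(np.abs(np.asarray(t, dtype=float)), 0.0, 1.0)
    return 2 * t**3 - 3 * t**2 + 1


def resample(volume: LabeledVolume, frame: PlaneFrame, extent: float | None = None) -> PlanarSlice:
    """Resample a labeled volume into a plane.

    Every output pixel blends the 8 voxels at the corners of its
    enclosing cell with weights w(t) = 2t^3 - 3t^2 + 1 per axis
    (t = per-axis distance in voxel units), multiplied across axes and
    normalized.  Labels are assigned by weighted majority of label mass;
    the intensity channel is the blended label value (useful for visual
    checks against the label image).
    """
    if extent is not None and extent != frame.extent:
        frame = PlaneFrame(frame.origin, frame.basis, frame.pixel_spacing, extent)
    n = frame.n_pixels
    ij = np.stack(np.meshgrid(np.arange(n), np.arange(n), indexing="ij"), axis=-1)
    uv = frame.pixel_to_plane(ij.reshape(-1, 2))
    world = frame.plane_to_world(uv)

    inv = np.linalg.inv(volume.affine)
    idx = (inv[:3, :3] @ world.T).T + inv[:3, 3]
    base = np.floor(idx).astype(int)
    frac = idx - base

    shape = np.array(volume.voxels.shape)
    inside = np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=1)
    if not inside.any():
        raise GeometryError("slice plane lies fully outside the volume")

    n_labels = int(volume.voxels.max()) + 1
    mass = np.zeros((len(idx), n_labels))
    wsum = np.zeros(len(idx))
    value = np.zeros(len(idx))
    for corner in range(8):
        offs = np.array([(corner >> k) & 1 for k in range(3)])
        cidx = base + offs
        valid = np.all((cidx >= 0) & (cidx < shape), axis=1)
        t = np.abs(frac - offs)
        w = cubic_weight(t).prod(axis=1)
        w = np.where(valid, w, 0.0)
        ci = np.clip(cidx, 0, shape - 1)
        lab = volume.voxels[ci[:, 0], ci[:, 1], ci[:, 2]]
        mass[np.arange(len(idx)), lab] += w
        value += w * lab
        wsum += w
    ok = wsum > 0
    labels = np.zeros(len(idx), dtype=volume.voxels.dtype)
    labels[ok] = np.argmax(mass[ok], axis=1)
    value[ok] = value[ok] / wsum[ok]
    return PlanarSlice(
        image=labels.reshape(n, n),
        intensity=value.reshape(n, n),
        frame=frame,
    )


def slice_circle(sphere: Sphere, frame: PlaneFrame) -> tuple[np.ndarray, float]:
    """Intersection of a sphere with the slice plane: in-plane center and
    radius rho = sqrt(r^2 - d^2), d the center-to-plane distance."""
    d = float(frame.plane_distance(sphere.cent)[0])
    if abs(d) >= sphere.r:
        raise GeometryError(
            f"plane misses the sphere (|d|={abs(d):.3f} mm >= r={sphere.r:.3f} mm)"
        )
    rho = math.sqrt(sphere.r**2 - d**2)
    center2d = frame.world_to_plane(sphere.cent)[0]
    return center2d, rho
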