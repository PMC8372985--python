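"""Core data containers shared across the pipeline.

All world coordinates are millimetres in a right-handed frame with
X = mediolateral (lateral positive, right-shoulder convention),
Y = parallel to the humeral diaphysis (proximal positive),
Z completing the right-handed frame (anterior positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """A geometric construction is impossible or degenerate."""


class FitError(ValueError):
    """A least-squares fit cannot proceed (degenerate or exhausted data)."""


@dataclass(frozen=True)
class Sphere:
    """A sphere in world coordinates: used for the implant (ILSS) and the
    acromial reference sphere."""

    cent: np.ndarray  # (3,) mm
    r: float  # mm

    def __post_init__(self):
        object.__setattr__(self, "cent", np.asarray(self.cent, dtype=float))
        if self.cent.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        if not self.r > 0:
            raise ValueError(f"sphere radius must be positive, got {self.r}")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Radial distance of points from the surface (positive outside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.linalg.norm(pts - self.cent, axis=-1) - self.r


@dataclass(frozen=True)
class OrientedPointCloud:
    """Points with unit normals, tagged by the anatomical structure they
    were sampled from."""

    points: np.ndarray  # (N, 3) mm
    normals: np.ndarray  # (N, 3) unit vectors
    label: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        nrm = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if pts.shape != nrm.shape:
            raise ValueError("points and normals must have matching shapes")
        norms = np.linalg.norm(nrm, axis=1)
        if len(nrm) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length (within 1e-6)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "normals", nrm)

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, idx) -> "OrientedPointCloud":
        return OrientedPointCloud(self.points[idx], self.normals[idx], self.label)


# Label codes for segmentation volumes.
LABELS = {"background": 0, "deltoid": 1, "acromion": 2, "clavicle": 3, "diaphysis": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class LabeledVolume:
    """3D integer-label grid with voxel spacing and a voxel->world affine.

    Voxel indices are 0-based; world = affine @ (i, j, k, 1).
    """

    voxels: np.ndarray  # (nx, ny, nz) integer labels
    spacing: np.ndarray  # (3,) mm, strictly positive
    affine: np.ndarray  # (4, 4) voxel -> world (mm)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")
        bad = set(np.unique(self.voxels)) - set(LABELS.values())
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    def world_coordinates(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ hom.T).T[:, :3]


@dataclass(frozen=True)
class Line2D:
    """An oriented line in slice (plane) coordinates."""

    point: np.ndarray  # (2,) mm
    direction: np.ndarray  # (2,) unit vector

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            d = d / n
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)

    def distance_to(self, q: np.ndarray) -> float:
        """Perpendicular distance from a point to the line."""
        q = np.asarray(q, dtype=float)
        v = q - self.point
        return abs(v[0] * self.direction[1] - v[1] * self.direction[0])


@dataclass(frozen=True)
class AngleSet:
    """The slice angles of the string-on-pulley model, in degrees.

    E: angle between the MD line (distal fiber) and the humeral diaphysis
       axis; B: the fiber's change of direction at the pulley; T = B/2.
    """

    E: float
    B: float

    def __post_init__(self):
        if not (0 <= self.E < 90):
            raise ValueError(f"E must be in [0, 90), got {self.E}")
        if not (0 < self.B < 180):
            raise ValueError(f"B must be in (0, 180), got {self.B}")

    @property
    def T(self) -> float:
        return self.B / 2.0


@dataclass(frozen=True)
class TangentConstruction:
    """The 2D tangent-line construction on one slice: MD line (distal
    insertion to pulley), proximal line (pulley to acromial insertion),
    diaphysis axis, and the associated contact/insertion points."""

    md_line: Line2D
    proximal_line: Line2D
    diaphysis_axis: Line2D
    contact_md: np.ndarray  # (2,) mm, on the circle
    contact_prox: np.ndarray  # (2,) mm, on the circle
    dip2d: np.ndarray  # distal insertion point, slice coords
    pip2d: np.ndarray  # proximal insertion point, slice coords


@dataclass(frozen=True)
class InsertionSite:
    """A labeled proximal insertion point on the acromial arc."""

    label: str  # one of A2, A3, M1, P1
    position: np.ndarray  # (3,) mm
    arc_index: int

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.label not in ("A2", "A3", "M1", "P1"):
            raise ValueError(f"unknown insertion label {self.label!r}")


# Insertion band -> slice mapping (S4=A2 ... S1=P1).
SITE_TO_SLICE = {"P1": "S1", "M1": "S2", "A3": "S3", "A2": "S4"}
SLICE_TO_SITE = {v: k for k, v in SITE_TO_SLICE.items()}
SLICE_LABELS = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class ForceSystem:
    """Planar static force system of the middle deltoid treated as an
    inextensible string over a frictionless pulley (F1 = F2)."""

    F1: float
    F2: float
    R: np.ndarray  # (2,) reaction on the MD, slice coords (x, y)
    Rprime: np.ndarray  # action of the MD on the pulley = -R
    F1prime: np.ndarray  # action of the MD at the distal insertion = -F1 vec
    Ry: float  # axial (Y'Y) component of R
    F1prime_y: float  # axial component of F'1

    def __post_init__(self):
        for name in ("R", "Rprime", "F1prime"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
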