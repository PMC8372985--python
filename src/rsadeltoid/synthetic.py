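"""Parametric post-RSA shoulder phantom with analytic ground truth.

The generator emulates the geometry this pipeline measures on patient
MRI: a spherical implant contact surface (the glenosphere region), a
cylindrical humeral diaphysis, an acromial spherical patch carrying the
four Sakoma insertion bands (P1, M1, A3, A2), and a middle-deltoid sheet
that wraps the implant sphere tangentially from the acromial arc down to
the distal insertion on the deltoid V.  Because every fiber path is
built from closed-form tangent geometry, the angles E/B/T, the CER, the
moment arm and the pulley circle of every slice are known exactly and
serve as oracles for the measurement pipeline.

World frame: mm; X mediolateral (lateral positive, right shoulder),
Y parallel to the humeral diaphysis (proximal positive), Z anterior.
The implant sphere is centered at the origin at 0 mm lateralization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .biomech import cer as _cer
from .biomech import dma as _dma
from .biomech import lateralize
from .reslice import (
    AcromialArc,
    PlaneFrame,
    insertion_points,
    plane_from_three_points,
    slice_circle,
)
from .slicegeom import build_wrap, measure_angles
from .types import (
    LABELS,
    AngleSet,
    GeometryError,
    InsertionSite,
    LabeledVolume,
    OrientedPointCloud,
    SITE_TO_SLICE,
    Sphere,
)

# Mean ILSS radius of the study cohort, used as the reference implant size.
REFERENCE_IMPLANT_RADIUS = 32.89

# The seven per-patient ILSS radii printed by the study (mm).
STUDY_ILSS_RADII = (31.25, 36.30, 33.64, 25.72, 39.42, 32.16, 31.75)


@dataclass(frozen=True)
class ShoulderParams:
    """Full parameter set of the synthetic post-RSA shoulder."""

    implant_center: np.ndarray  # (3,) mm
    implant_radius: float  # mm
    diaphysis_axis: np.ndarray  # unit 3-vector (Y'Y direction)
    diaphysis_point: np.ndarray  # a point on the shaft axis
    diaphysis_radius: float  # mm
    diaphysis_extent: tuple[float, float]  # y-range of the shaft, mm
    distal_insertion: np.ndarray  # DIP, mm
    acromial_center: np.ndarray  # (3,) mm
    acromial_radius: float  # mm
    insertion_sites: tuple[InsertionSite, ...]  # P1, M1, A3, A2
    deltoid_thickness: float = 5.0  # mm, voxelization realism only
    voxel_spacing: np.ndarray = field(
        default_factory=lambda: np.array([1.5, 1.5, 3.0])
    )
    arm_angle: float = 80.0  # humerus-scapula angle the phantom emulates
    noise_sd: float = 0.0  # mm, per-point selection error of sampled picks
    outlier_fraction: float = 0.0  # fraction of off-sphere deltoid picks
    seed: int = 0

    def __post_init__(self):
        for name in (
            "implant_center",
            "diaphysis_axis",
            "diaphysis_point",
            "distal_insertion",
            "acromial_center",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "voxel_spacing", np.asarray(self.voxel_spacing, dtype=float))
        if self.implant_radius <= 0:
            raise ValueError("implant radius must be positive")
        if not np.all(self.voxel_spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")
        n = np.linalg.norm(self.diaphysis_axis)
        if abs(n - 1) > 1e-9:
            object.__setattr__(self, "diaphysis_axis", self.diaphysis_axis / n)
        # DIP must be distal to the implant along the shaft axis and outside it.
        rel = self.distal_insertion - self.implant_center
        if rel @ self.diaphysis_axis >= 0:
            raise GeometryError("DIP must lie distal to the implant along the shaft axis")
        if np.linalg.norm(rel) <= self.implant_radius:
            raise GeometryError("DIP lies inside the implant sphere")
        labels = [s.label for s in self.insertion_sites]
        if labels != ["P1", "M1", "A3", "A2"]:
            raise GeometryError(
                f"insertion sites must be ordered P1, M1, A3, A2; got {labels}"
            )
        for s in self.insertion_sites:
            if np.linalg.norm(s.position - self.implant_center) <= self.implant_radius:
                raise GeometryError(f"insertion site {s.label} lies inside the implant sphere")

    @property
    def diaphysis_center(self) -> np.ndarray:
        y0, y1 = self.diaphysis_extent
        mid = 0.5 * (y0 + y1)
        p, a = self.diaphysis_point, self.diaphysis_axis
        t = (mid - p[1]) / a[1]
        return p + t * a


@dataclass
class GroundTruth:
    """Closed-form per-slice, per-offset quantities of a phantom."""

    sphere: Sphere
    per_slice: dict  # (slice_label, offset) -> dict(angles, cer, dma, rho, circle)

    def angles(self, slice_label: str, offset: float) -> AngleSet:
        return self.per_slice[(slice_label, float(offset))]["angles"]

    def cer(self, slice_label: str, offset: float) -> float:
        return self.per_slice[(slice_label, float(offset))]["cer"]


def reference_arc(
    implant_radius: float = REFERENCE_IMPLANT_RADIUS,
    acromial_center=None,
    acromial_radius: float | None = None,
    elevation_deg: float = -4.8,
    start_deg: float = -30.0,
    span_deg: float = 60.0,
) -> AcromialArc:
    """Acromial arc of the reference phantom, scaled with implant size."""
    s = implant_radius / REFERENCE_IMPLANT_RADIUS
    if acromial_center is None:
        acromial_center = np.array([-9.02, 35.78, -1.55]) * s
    if acromial_radius is None:
        acromial_radius = 12.22 * s
    return AcromialArc(
        center=np.asarray(acromial_center, dtype=float),
        radius=float(acromial_radius),
        start_deg=start_deg,
        span_deg=span_deg,
        elevation_deg=elevation_deg,
    )


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def reference_params(
    implant_radius: float = REFERENCE_IMPLANT_RADIUS,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    site_indices: tuple[int, int, int, int] = (0, 1, 5, 6),
    jitter: float = 0.0,
    arm_angle: float = 80.0,
) -> ShoulderParams:
    """The reference post-RSA phantom.

    The geometry encodes the supine imaging position with the arm at 80
    degrees of humerothoracic abduction, expressed in the humerus-fixed
    frame: the acromial complex sits medial and only moderately proximal
    to the implant, so the deltoid wraps the implant sphere through a
    large arc.  ``arm_angle`` rotates the scapular complex about the
    implant center relative to that reference position (the mapping from
    arm position to relative geometry is otherwise unconstrained and is
    exposed here as a free parameter).

    All lengths scale with the implant radius, so phantoms with the
    study's per-patient radii share the same wrap angles up to the
    seeded ``jitter`` (mm) applied to the acromial and distal landmarks.
    """
    s = implant_radius / REFERENCE_IMPLANT_RADIUS
    rng = np.random.default_rng(seed)

    def j(scale=1.0):
        return rng.normal(0.0, jitter * scale, size=3) if jitter > 0 else np.zeros(3)

    arc = reference_arc(
        implant_radius,
        acromial_center=np.array([-9.02, 35.78, -1.55]) * s + j(0.8),
    )
    sites = insertion_points(arc, step_degrees=10.0, site_indices=site_indices)
    acromial_center = arc.center
    if abs(arm_angle - 80.0) > 1e-12:
        rot = _rot_z(arm_angle - 80.0)
        acromial_center = rot @ acromial_center
        sites = [
            InsertionSite(st.label, rot @ st.position, st.arc_index) for st in sites
        ]
    dip = np.array([13.86, -146.18, -0.75]) * s + j()
    return ShoulderParams(
        implant_center=np.zeros(3),
        implant_radius=float(implant_radius),
        diaphysis_axis=np.array([0.0, 1.0, 0.0]),
        diaphysis_point=np.array([2.61, 0.0, 0.0]) * s,
        diaphysis_radius=11.0 * s,
        diaphysis_extent=(-170.0 * s, -38.0 * s),
        distal_insertion=dip,
        acromial_center=acromial_center,
        acromial_radius=arc.radius,
        insertion_sites=tuple(sites),
        arm_angle=float(arm_angle),
        noise_sd=noise_sd,
        outlier_fraction=outlier_fraction,
        seed=seed,
    )


def patient_cohort(
    radii=STUDY_ILSS_RADII, noise_sd: float = 0.0, jitter: float = 1.0, seed: int = 0
) -> list[ShoulderParams]:
    """Synthetic cohort with the study's per-patient implant radii and
    seeded anatomical variation of the landmark geometry.

    Each jittered phantom is validated against the wrap construction on
    every slice and offset; draws that leave the string detached or an
    insertion inside the pulley are resampled deterministically.
    """
    cohort = []
    for i, r in enumerate(radii):
        for attempt in range(20):
            try:
                params = reference_params(
                    implant_radius=r,
                    noise_sd=noise_sd,
                    seed=(seed * 1009 + i * 101 + attempt * 7919) % (2**31 - 1),
                    jitter=jitter,
                )
                ground_truth(params)
            except GeometryError:
                continue
            cohort.append(params)
            break
        else:
            raise GeometryError(
                f"could not draw a valid phantom for radius {r} after 20 attempts"
            )
    return cohort


def landmarks_from_params(params: ShoulderParams) -> dict:
    return {
        "sites": list(params.insertion_sites),
        "dip": params.distal_insertion.copy(),
        "acromial_center": params.acromial_center.copy(),
        "diaphysis_center": params.diaphysis_center,
    }


def _slice_frame(params: ShoulderParams, site: InsertionSite) -> PlaneFrame:
    return plane_from_three_points(
        params.acromial_center,
        site.position,
        params.diaphysis_center,
        axis_direction=params.diaphysis_axis,
    )


def _wrap_in_plane(params: ShoulderParams, frame: PlaneFrame, sphere: Sphere):
    circle = slice_circle(sphere, frame)
    dip2d = frame.world_to_plane(params.distal_insertion)[0]
    return circle, dip2d


def analytic_angles(
    params: ShoulderParams, slice_label: str, offset: float = 0.0
) -> AngleSet:
    """Closed-form slice angles from the true phantom geometry.

    E comes from the external tangent from the (projected) distal
    insertion to the in-plane pulley circle; B from the tangent pair's
    change of direction; T = B/2.
    """
    site = next(
        s for s in params.insertion_sites if SITE_TO_SLICE[s.label] == slice_label
    )
    frame = _slice_frame(params, site)
    sphere = lateralize(Sphere(params.implant_center, params.implant_radius), offset)
    circle, dip2d = _wrap_in_plane(params, frame, sphere)
    pip2d = frame.world_to_plane(site.position)[0]
    construction = build_wrap(dip2d, pip2d, circle)
    return measure_angles(construction)


def ground_truth(
    params: ShoulderParams,
    offsets=(0.0, 6.0, 9.0, 12.0),
    dma_variant: str = "perpendicular_to_F1_line",
) -> GroundTruth:
    """Exact per-slice, per-offset angles, CER, DMA and pulley radius."""
    sphere0 = Sphere(params.implant_center, params.implant_radius)
    per_slice = {}
    for site in params.insertion_sites:
        slice_label = SITE_TO_SLICE[site.label]
        frame = _slice_frame(params, site)
        pip2d = frame.world_to_plane(site.position)[0]
        for offset in offsets:
            sphere = lateralize(sphere0, float(offset))
            circle, dip2d = _wrap_in_plane(params, frame, sphere)
            construction = build_wrap(dip2d, pip2d, circle)
            angles = measure_angles(construction)
            per_slice[(slice_label, float(offset))] = {
                "angles": angles,
                "cer": _cer(angles),
                "dma": _dma(construction, circle, dma_variant),
                "rho": circle[1],
                "circle_center": circle[0],
            }
    return GroundTruth(sphere=sphere0, per_slice=per_slice)


# ---------------------------------------------------------------------------
# Fiber paths and point clouds
# ---------------------------------------------------------------------------


def _fiber_path(params: ShoulderParams, theta_deg: float, arc: AcromialArc,
                n_points: int = 120) -> tuple[np.ndarray, np.ndarray]:
    """Sample one deltoid fiber (DIP -> wrap arc -> arc point) in 3D.

    Returns (points, on_sphere_mask): points along the taut path; the
    mask flags the pulley-contact portion, which lies exactly on the
    implant sphere.
    """
    proximal = arc.point_at(theta_deg)
    frame = plane_from_three_points(
        params.acromial_center, proximal, params.diaphysis_center,
        axis_direction=params.diaphysis_axis,
    )
    sphere = Sphere(params.implant_center, params.implant_radius)
    circle, dip2d = _wrap_in_plane(params, frame, sphere)
    pip2d = frame.world_to_plane(proximal)[0]
    construction = build_wrap(dip2d, pip2d, circle)

    center, rho = construction.md_line, circle[1]
    c2d = circle[0]
    c1, c2 = construction.contact_md, construction.contact_prox
    a1 = math.atan2(c1[1] - c2d[1], c1[0] - c2d[0])
    a2 = math.atan2(c2[1] - c2d[1], c2[0] - c2d[0])
    # Traverse the wrap counterclockwise from the MD contact.
    while a2 < a1:
        a2 += 2 * math.pi
    seg_lengths = np.array([
        np.linalg.norm(c1 - dip2d),
        (a2 - a1) * rho,
        np.linalg.norm(pip2d - c2),
    ])
    n_seg = np.maximum(2, np.round(n_points * seg_lengths / seg_lengths.sum()).astype(int))

    t1 = np.linspace(0, 1, n_seg[0], endpoint=False)[:, None]
    seg1 = dip2d + t1 * (c1 - dip2d)
    ang = np.linspace(a1, a2, n_seg[1], endpoint=False)
    seg2 = c2d + rho * np.column_stack([np.cos(ang), np.sin(ang)])
    t3 = np.linspace(0, 1, n_seg[2])[:, None]
    seg3 = c2 + t3 * (pip2d - c2)

    uv = np.vstack([seg1, seg2, seg3])
    on_sphere = np.zeros(len(uv), dtype=bool)
    on_sphere[n_seg[0]: n_seg[0] + n_seg[1]] = True
    return frame.plane_to_world(uv), on_sphere


def _click_jitter(points: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-point selection error of RMS magnitude ``sd`` mm
    (manual picks err independently from click to click, unlike the
    spatially correlated boundary noise of a repeat segmentation, which
    perturb_segmentation models separately)."""
    if sd == 0 or len(points) == 0:
        return np.zeros_like(points)
    return rng.normal(0.0, sd / math.sqrt(3.0), size=points.shape)


def _deltoid_internal_cloud(
    params: ShoulderParams, arc: AcromialArc, rng: np.random.Generator,
    n_fibers: int = 48, n_points: int = 110,
) -> OrientedPointCloud:
    """Emulated manual picks on the deltoid's internal aspect: points on
    the pulley-contact band (exactly on the implant sphere), with
    normals toward the implant center, plus an optional fraction of
    off-sphere picks along the straight fiber segments."""
    thetas = np.linspace(arc.start_deg + 2, arc.start_deg + arc.span_deg - 2, n_fibers)
    contact, stray = [], []
    for th in thetas:
        try:
            pts, on_sphere = _fiber_path(params, th, arc, n_points=n_points)
        except GeometryError:
            # Fibers beyond the wrap region run straight; no contact picks.
            continue
        contact.append(pts[on_sphere])
        stray.append(pts[~on_sphere])
    if not contact:
        raise GeometryError("no deltoid fiber wraps the implant sphere")
    contact = np.vstack(contact)
    center = params.implant_center
    points = [contact]
    normals = [(center - contact) / np.linalg.norm(center - contact, axis=1, keepdims=True)]
    if params.outlier_fraction > 0:
        stray = np.vstack(stray)
        # Mis-picks happen near the implant (on the straight fiber runs just
        # off the contact band), not halfway down the arm.
        near = (
            np.abs(np.linalg.norm(stray - center, axis=1) - params.implant_radius)
            < 0.35 * params.implant_radius
        )
        stray = stray[near]
        n_out = int(round(params.outlier_fraction * len(contact) / (1 - params.outlier_fraction)))
        pick = rng.choice(len(stray), size=min(n_out, len(stray)), replace=False)
        out_pts = stray[pick]
        out_nrm = (center - out_pts) / np.linalg.norm(center - out_pts, axis=1, keepdims=True)
        # Half of the stray picks carry flipped (external-aspect) normals.
        flip = rng.random(len(out_pts)) < 0.5
        out_nrm[flip] *= -1
        points.append(out_pts)
        normals.append(out_nrm)
    pts = np.vstack(points)
    nrm = np.vstack(normals)
    pts = pts + _click_jitter(pts, params.noise_sd, rng)
    return OrientedPointCloud(points=pts, normals=nrm, label="deltoid_internal")


def _acromion_cloud(
    params: ShoulderParams, arc: AcromialArc, rng: np.random.Generator,
    n_points: int = 400,
) -> OrientedPointCloud:
    """Spherical patch on the acromial reference sphere (undersurface of
    the acromion), normals toward the acromial center."""
    th = rng.uniform(arc.start_deg, arc.start_deg + arc.span_deg, n_points)
    el = rng.uniform(arc.elevation_deg - 18.0, arc.elevation_deg + 18.0, n_points)
    th, el = np.radians(th), np.radians(el)
    d = np.column_stack([np.cos(el) * np.cos(th), np.sin(el), np.cos(el) * np.sin(th)])
    pts = params.acromial_center + params.acromial_radius * d
    pts = pts + _click_jitter(pts, params.noise_sd, rng)
    nrm = (params.acromial_center - pts)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return OrientedPointCloud(points=pts, normals=nrm, label="acromion")


def _diaphysis_cloud(
    params: ShoulderParams, rng: np.random.Generator, n_rings: int = 40,
    n_per_ring: int = 24,
) -> OrientedPointCloud:
    """Cylindrical shaft surface, rings symmetric about the shaft center
    so the cloud centroid sits on the axis midpoint."""
    y0, y1 = params.diaphysis_extent
    ys = np.linspace(y0, y1, n_rings)
    phis = np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False)
    a = params.diaphysis_axis
    # Orthonormal frame around the shaft axis.
    e1 = np.cross(a, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(a, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    p0 = params.diaphysis_point
    pts, nrm = [], []
    for y in ys:
        t = (y - p0[1]) / a[1]
        axis_pt = p0 + t * a
        ring_n = np.outer(np.cos(phis), e1) + np.outer(np.sin(phis), e2)
        pts.append(axis_pt + params.diaphysis_radius * ring_n)
        nrm.append(ring_n)
    pts = np.vstack(pts)
    nrm = np.vstack(nrm)
    pts = pts + _click_jitter(pts, params.noise_sd, rng)
    return OrientedPointCloud(points=pts, normals=nrm, label="diaphysis")


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _world_grid(params: ShoulderParams):
    r = params.implant_radius
    lo = np.array([-2.6 * r, params.diaphysis_extent[0] - 8.0, -1.8 * r])
    hi = np.array([1.6 * r, params.acromial_center[1] + params.acromial_radius + 8.0, 1.8 * r])
    spacing = params.voxel_spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = lo
    return shape, affine


def voxelize(params: ShoulderParams, seed: int | None = None) -> LabeledVolume:
    """Rasterize the phantom into a labeled volume (bg/deltoid/acromion/
    clavicle/diaphysis), voxel spacing from the parameters."""
    arc = AcromialArc(
        center=params.acromial_center,
        radius=params.acromial_radius,
        start_deg=_arc_start(params),
        span_deg=_arc_span(params),
        elevation_deg=_arc_elevation(params),
    )
    shape, affine = _world_grid(params)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * params.voxel_spacing + affine[:3, 3]

    labels = np.zeros(len(world), dtype=np.uint8)

    # Humeral diaphysis: cylinder.
    a, p0 = params.diaphysis_axis, params.diaphysis_point
    rel = world - p0
    tt = rel @ a
    radial = np.linalg.norm(rel - np.outer(tt, a), axis=1)
    y = world[:, 1]
    in_shaft = (radial <= params.diaphysis_radius) & (y >= params.diaphysis_extent[0]) & (
        y <= params.diaphysis_extent[1]
    )
    labels[in_shaft] = LABELS["diaphysis"]

    # Acromion: shell of the acromial sphere over the arc's angular range.
    rel_a = world - params.acromial_center
    dist_a = np.linalg.norm(rel_a, axis=1)
    shell = np.abs(dist_a - params.acromial_radius) <= 2.5
    with np.errstate(invalid="ignore", divide="ignore"):
        el = np.degrees(np.arcsin(np.clip(rel_a[:, 1] / np.maximum(dist_a, 1e-9), -1, 1)))
        az = np.degrees(np.arctan2(rel_a[:, 2], rel_a[:, 0]))
    in_patch = (
        shell
        & (el >= _arc_elevation(params) - 18)
        & (el <= _arc_elevation(params) + 18)
        & (az >= _arc_start(params) - 5)
        & (az <= _arc_start(params) + _arc_span(params) + 5)
    )
    labels[in_patch & (labels == 0)] = LABELS["acromion"]

    # Clavicle: anterior-medial horizontal rod (cosmetic).
    clav_axis_pt = params.acromial_center + np.array([-10.0, 4.0, 0.0])
    rel_c = world - clav_axis_pt
    rad_c = np.sqrt(rel_c[:, 0] ** 2 + rel_c[:, 1] ** 2)
    in_clav = (rad_c <= 6.0) & (rel_c[:, 2] >= 0) & (rel_c[:, 2] <= 60.0)
    labels[in_clav & (labels == 0)] = LABELS["clavicle"]

    # Deltoid sheet: tube of half-thickness around the fiber paths.
    sheet = []
    thetas = np.linspace(arc.start_deg + 2, arc.start_deg + arc.span_deg - 2, 36)
    for th in thetas:
        try:
            pts, _ = _fiber_path(params, th, arc, n_points=140)
        except GeometryError:
            # Non-wrapping edge fiber: straight run from DIP to the arc point.
            t = np.linspace(0.0, 1.0, 140)[:, None]
            pts = params.distal_insertion + t * (arc.point_at(th) - params.distal_insertion)
        sheet.append(pts)
    sheet = np.vstack(sheet)
    tree = cKDTree(sheet)
    half = params.deltoid_thickness / 2.0
    # Restrict the query to a band around the sheet's bounding box.
    pad = half + float(params.voxel_spacing.max())
    lo, hi = sheet.min(axis=0) - pad, sheet.max(axis=0) + pad
    cand = np.all((world >= lo) & (world <= hi), axis=1) & (labels == 0)
    d, _ = tree.query(world[cand], k=1, distance_upper_bound=half + 1e-9)
    hit = np.where(cand)[0][np.isfinite(d) & (d <= half)]
    labels[hit] = LABELS["deltoid"]

    return LabeledVolume(
        voxels=labels.reshape(shape), spacing=params.voxel_spacing, affine=affine
    )


def _arc_start(params: ShoulderParams) -> float:
    return _site_geometry(params)[0]


def _arc_span(params: ShoulderParams) -> float:
    return _site_geometry(params)[1]


def _arc_elevation(params: ShoulderParams) -> float:
    return _site_geometry(params)[2]


def _site_geometry(params: ShoulderParams) -> tuple[float, float, float]:
    """Recover arc start/span/elevation from the stored insertion sites."""
    rel = np.array([s.position for s in params.insertion_sites]) - params.acromial_center
    rel /= np.linalg.norm(rel, axis=1, keepdims=True)
    el = float(np.degrees(np.arcsin(rel[:, 1].mean())))
    az = np.degrees(np.arctan2(rel[:, 2], rel[:, 0]))
    lo, hi = float(az.min()), float(az.max())
    pad = 6.0
    return lo - pad, (hi - lo) + 2 * pad, el


def generate_shoulder(
    params: ShoulderParams, seed: int | None = None, with_volume: bool = True
) -> tuple[LabeledVolume | None, dict, GroundTruth]:
    """Generate the phantom: labeled volume, per-structure oriented point
    clouds, and closed-form ground truth.

    Deterministic: identical (params, seed) give identical output.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    arc = AcromialArc(
        center=params.acromial_center,
        radius=params.acromial_radius,
        start_deg=_arc_start(params),
        span_deg=_arc_span(params),
        elevation_deg=_arc_elevation(params),
    )
    clouds = {
        "deltoid_internal": _deltoid_internal_cloud(params, arc, rng),
        "acromion": _acromion_cloud(params, arc, rng),
        "diaphysis": _diaphysis_cloud(params, rng),
    }
    truth = ground_truth(params)
    volume = voxelize(params) if with_volume else None
    return volume, clouds, truth


def perturb_segmentation(
    volume: LabeledVolume, noise_sd: float, seed: int = 0
) -> LabeledVolume:
    """Displace label boundaries by a smooth random field of RMS amplitude
    ``noise_sd`` mm, emulating a repeat manual segmentation.

    noise_sd = 0 returns an identical copy; identical seeds reproduce
    identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return LabeledVolume(volume.voxels.copy(), volume.spacing.copy(), volume.affine.copy())
    rng = np.random.default_rng(seed)
    shape = volume.voxels.shape
    coarse = np.maximum(3, np.array(shape) // 3)
    disp = []
    for axis in range(3):
        field_c = rng.normal(size=tuple(coarse))
        field_f = ndimage.zoom(field_c, np.array(shape) / coarse, order=3)
        field_f = field_f[: shape[0], : shape[1], : shape[2]]
        pad = [(0, shape[i] - field_f.shape[i]) for i in range(3)]
        field_f = np.pad(field_f, pad, mode="edge")
        disp.append(field_f)
    disp = np.stack(disp)
    rms = np.sqrt((disp**2).mean())
    disp *= noise_sd / rms  # mm
    coords = np.indices(shape).astype(float)
    for axis in range(3):
        coords[axis] += disp[axis] / volume.spacing[axis]
    warped = ndimage.map_coordinates(volume.voxels, coords, order=0, mode="nearest")
    return LabeledVolume(warped, volume.spacing.copy(), volume.affine.copy())


def extract_surface_clouds(volume: LabeledVolume) -> dict:
    """Oriented surface point clouds from a labeled volume via marching
    cubes, emulating surface reconstruction of a manual segmentation.

    The deltoid cloud's normals are re-oriented toward the concave
    (implant-facing) side using a rough all-points sphere fit, matching
    the internal-aspect picking convention.
    """
    from skimage import measure

    clouds = {}
    for name, code in (("deltoid_internal", 1), ("acromion", 2), ("diaphysis", 4)):
        mask = (volume.voxels == code).astype(float)
        if mask.sum() == 0:
            continue
        verts, faces, vnormals, _ = measure.marching_cubes(
            mask, level=0.5, spacing=tuple(volume.spacing)
        )
        pts = verts + volume.affine[:3, 3]
        nrm = vnormals / np.linalg.norm(vnormals, axis=1, keepdims=True)
        if name == "deltoid_internal":
            # Picks are made on the internal aspect next to the implant:
            # keep the proximal part of the muscle (the wrap region), use a
            # rough all-points sphere there to orient the selection, then
            # keep the concave-side vertices.
            y0, y1 = pts[:, 1].min(), pts[:, 1].max()
            proximal = pts[:, 1] > y0 + 0.60 * (y1 - y0)
            pts, nrm = pts[proximal], nrm[proximal]
            rough = _rough_sphere(pts)
            for _ in range(2):  # self-consistent internal-aspect selection
                toward = rough - pts
                toward /= np.linalg.norm(toward, axis=1, keepdims=True)
                facing = (nrm * toward).sum(axis=1) > 0.3
                from .spherefit import FitConfig, iterate_fit

                sphere, _diag = iterate_fit(
                    OrientedPointCloud(pts[facing], toward[facing], name),
                    FitConfig(),
                )
                rough = sphere.cent
            pts, nrm = pts[facing], toward[facing]
        clouds[name] = OrientedPointCloud(points=pts, normals=nrm, label=name)
    return clouds


def _rough_sphere(points: np.ndarray) -> np.ndarray:
    """Crude algebraic sphere center through all points (initialization
    for internal-aspect selection)."""
    A = np.column_stack([2 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]
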