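"""Static force model of the middle deltoid after reverse shoulder
arthroplasty.

The muscle is an inextensible, massless string wrapping the implant
sphere like a pulley, loaded with equal tensions F1 = F2 at its distal
and proximal insertions.  Projecting the static equilibrium
F1 + F2 + R = 0 on the humeral diaphysis axis (Y'Y) gives

    Ry      = F1 cos(E) + F1 cos(2T + E) = 2 F1 cos(T) cos(T + E)
    F'1y    = F1 cos(E)

and the Coaptation/Elevation Ratio

    CER = |R'y / F'1y| = |2 cos(T) cos(T + E) / cos(E)|,

the ratio of the axial head-centering (coapting) force to the axial
elevating force.  CER is dimensionless; values near 1 indicate a deltoid
acting as much as a stabilizer as an elevator.

Glenosphere lateralization is simulated by translating the implant
sphere along the world X axis (radius unchanged), re-intersecting it
with the fixed slice planes and re-measuring the angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .slicegeom import Circle, build_wrap, measure_angles
from .types import (
    AngleSet,
    ForceSystem,
    GeometryError,
    Sphere,
    TangentConstruction,
)

DMA_VARIANTS = ("perpendicular_to_F1_line", "paper_perpendicular_line")
DEFAULT_OFFSETS = (0.0, 6.0, 9.0, 12.0)


def cer(angles: AngleSet) -> float:
    """Coaptation/Elevation Ratio |2 cos(T) cos(T+E) / cos(E)|.

    Reported as a positive magnitude: the derivation carries a minus sign
    (the coapting reaction opposes the elevating force along Y'Y), but
    study values are printed positive.
    """
    T, E = math.radians(angles.T), math.radians(angles.E)
    if angles.E >= 90 or math.cos(E) == 0:
        raise GeometryError("E >= 90 degrees: elevating component vanishes")
    return abs(2 * math.cos(T) * math.cos(T + E) / math.cos(E))


def force_components(F1: float, angles: AngleSet) -> ForceSystem:
    """Planar force system for tension F1 and measured angles.

    In the canonical slice frame the two tensions pull the string away
    from the pulley along the fiber segments: the distal segment makes
    angle E with the diaphysis axis, the proximal segment angle 2T + E,
    and the angle between the two segments is B = 2T.  The pulley
    reaction then has axial component
    Ry = F1 cos(E) + F1 cos(2T + E) = 2 F1 cos(T) cos(T + E)
    and magnitude |R| = 2 F1 cos(T).
    """
    if F1 <= 0:
        raise ValueError(f"F1 must be positive, got {F1}")
    E = math.radians(angles.E)
    BE = math.radians(2 * angles.T + angles.E)
    v1_away = np.array([math.sin(E), -math.cos(E)])  # toward the distal insertion
    v2_away = np.array([math.sin(BE), -math.cos(BE)])  # toward the proximal insertion
    F1vec = F1 * v1_away
    F2vec = F1 * v2_away
    R = -(F1vec + F2vec)
    return ForceSystem(
        F1=F1,
        F2=F1,
        R=R,
        Rprime=-R,
        F1prime=-F1vec,
        Ry=float(R[1]),
        F1prime_y=F1 * math.cos(E),
    )


def lateralize(sphere: Sphere, offset: float) -> Sphere:
    """Translate the implant sphere laterally (+X) by ``offset`` mm.

    The radius is unchanged (the implant geometry is assumed unaffected
    by lateralization)."""
    if offset < 0:
        raise ValueError("lateral offset must be non-negative")
    return Sphere(cent=sphere.cent + np.array([offset, 0.0, 0.0]), r=sphere.r)


def dma(
    construction: TangentConstruction,
    circle: Circle,
    variant: str = "perpendicular_to_F1_line",
) -> float:
    """Deltoid moment arm about the implant center, in mm.

    'perpendicular_to_F1_line': perpendicular distance from the in-plane
    implant center to the MD line of action (the classical moment arm;
    equal to the pulley radius for a tangent line).
    'paper_perpendicular_line': distance from the implant center to the
    line through the distal insertion point perpendicular to F1.
    """
    center = np.asarray(circle[0], dtype=float)
    if variant == "perpendicular_to_F1_line":
        return float(construction.md_line.distance_to(center))
    if variant == "paper_perpendicular_line":
        v1 = construction.md_line.direction
        return float(abs((center - construction.dip2d) @ v1))
    raise ValueError(f"unknown DMA variant {variant!r}; choose from {DMA_VARIANTS}")


@dataclass
class SliceResult:
    patient: str
    slice_label: str
    offset: float
    E: float
    B: float
    T: float
    cer: float
    dma: float
    dma_variant: str
    rho: float


def run_pipeline(
    volume_or_params,
    offsets=DEFAULT_OFFSETS,
    slices=("S1", "S2", "S3", "S4"),
    seed: int = 0,
    dma_variant: str = "perpendicular_to_F1_line",
    fit_config=None,
    patient: str = "P1",
    co_translate_humerus: bool = False,
) -> pd.DataFrame:
    """End-to-end static analysis for one shoulder.

    Accepts either ShoulderParams (the implant and acromial spheres are
    fitted to the generated oriented point clouds) or a LabeledVolume
    (surfaces are extracted from the segmentation first).  For each
    requested slice and lateral offset: fit the ILSS and the acromial
    sphere, build the three-point slice plane, translate the ILSS
    laterally, intersect it with the plane, construct the tangent wrap
    and emit angles, CER and DMA.

    ``co_translate_humerus`` additionally translates the distal
    insertion (and diaphysis landmarks) with the glenosphere, exploring
    the variant where the humerus is lateralized along with the implant;
    by default only the implant sphere moves.
    """
    from . import synthetic  # deferred: synthetic imports cer from this module
    from .reslice import plane_from_three_points, slice_circle
    from .spherefit import FitConfig, iterate_fit
    from .types import LabeledVolume

    if fit_config is None:
        fit_config = FitConfig()

    if isinstance(volume_or_params, synthetic.ShoulderParams):
        params = volume_or_params
        _, clouds, _ = synthetic.generate_shoulder(params, seed=seed)
        landmarks = synthetic.landmarks_from_params(params)
    elif isinstance(volume_or_params, LabeledVolume):
        clouds = synthetic.extract_surface_clouds(volume_or_params)
        landmarks = None
        params = None
    else:
        raise TypeError(
            "run_pipeline expects ShoulderParams or LabeledVolume, got "
            f"{type(volume_or_params).__name__}"
        )

    ilss, _ = iterate_fit(clouds["deltoid_internal"], fit_config)
    acromial_cfg = FitConfig(
        prune_fraction=0.0,
        max_iterations=fit_config.max_iterations,
        radius_tol=fit_config.radius_tol,
        normal_sign=fit_config.normal_sign,
    )
    acromial, _ = iterate_fit(clouds["acromion"], acromial_cfg)

    # Diaphysis axis and center from the segmented shaft surface.
    dia_pts = clouds["diaphysis"].points
    dia_center = dia_pts.mean(axis=0)
    u, s, vt = np.linalg.svd(dia_pts - dia_center, full_matrices=False)
    dia_axis = vt[0]
    if dia_axis[1] < 0:
        dia_axis = -dia_axis

    if landmarks is not None:
        sites = landmarks["sites"]
        dip = landmarks["dip"]
    else:
        raise GeometryError(
            "volume input requires insertion landmarks; pass ShoulderParams or "
            "use extract_surface_clouds + explicit landmarks via the library API"
        )

    rows = []
    for site in sites:
        slice_label = synthetic.SITE_TO_SLICE[site.label]
        if slice_label not in slices:
            continue
        frame = plane_from_three_points(
            acromial.cent, site.position, dia_center, axis_direction=dia_axis
        )
        for offset in offsets:
            moved = lateralize(ilss, float(offset))
            dip_w = dip + (np.array([offset, 0.0, 0.0]) if co_translate_humerus else 0.0)
            try:
                circle = slice_circle(moved, frame)
                dip2d = frame.world_to_plane(dip_w)[0]
                pip2d = frame.world_to_plane(site.position)[0]
                construction = build_wrap(dip2d, pip2d, circle)
                angles = measure_angles(construction)
                row_cer = cer(angles)
                row_dma = dma(construction, circle, dma_variant)
            except GeometryError as exc:
                raise GeometryError(
                    f"{patient}/{slice_label}/offset {offset} mm: {exc}"
                ) from exc
            rows.append(
                SliceResult(
                    patient=patient,
                    slice_label=slice_label,
                    offset=float(offset),
                    E=angles.E,
                    B=angles.B,
                    T=angles.T,
                    cer=row_cer,
                    dma=row_dma,
                    dma_variant=dma_variant,
                    rho=circle[1],
                ).__dict__
            )
    return pd.DataFrame(rows)


def run_cohort(
    params_list,
    offsets=DEFAULT_OFFSETS,
    slices=("S1", "S2", "S3", "S4"),
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run the pipeline over a cohort; one row per (patient, slice, offset)."""
    frames = []
    for i, params in enumerate(params_list):
        frames.append(
            run_pipeline(
                params,
                offsets=offsets,
                slices=slices,
                seed=seed + i,
                patient=f"P{i + 1}",
                **kwargs,
            )
        )
    return pd.concat(frames, ignore_index=True)
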