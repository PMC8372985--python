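"""Tangent-line geometry on a planar slice.

The middle deltoid is modeled as an inextensible string wrapping the
in-plane section of the implant sphere (a circle, the "pulley").  The
*MD line* runs from the distal insertion point (DIP) to its tangency on
the pulley; the *proximal line* runs from the pulley to the proximal
insertion point (PIP) on the acromion.  Angle E is measured between the
MD line and the humeral diaphysis axis, B is the fiber's change of
direction across the pulley, and T = B/2.
"""

from __future__ import annotations

import numpy as np

from .types import AngleSet, GeometryError, Line2D, TangentConstruction

Circle = tuple[np.ndarray, float]  # (center2d mm, radius mm)


def tangent_from_point(p, circle: Circle, side: str = "left") -> Line2D:
    """External tangent line from point ``p`` to a circle.

    The returned line is oriented from ``p`` toward its tangency point.
    ``side`` selects which of the two tangents: the one that keeps the
    circle center on the given side ('left' or 'right') of the oriented
    line.  For a right shoulder with the fiber traveling proximally on
    the lateral aspect, the center lies to the left of the MD line.
    """
    p = np.asarray(p, dtype=float)
    center, rho = np.asarray(circle[0], dtype=float), float(circle[1])
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    m = center - p
    dist = float(np.linalg.norm(m))
    if dist <= rho * (1 + 1e-12):
        raise GeometryError(
            f"point at distance {dist:.6g} is inside or on the circle (rho={rho:.6g}); "
            "no external tangent exists"
        )
    phi = np.arctan2(m[1], m[0])
    alpha = np.arcsin(rho / dist)
    # Direction phi - alpha keeps the center to the left of the ray.
    theta = phi - alpha if side == "left" else phi + alpha
    direction = np.array([np.cos(theta), np.sin(theta)])
    contact = p + dist * np.cos(alpha) * direction
    return Line2D(point=contact, direction=direction)


def tangent_contact(line: Line2D) -> np.ndarray:
    """Contact point stored as the line's anchor by ``tangent_from_point``."""
    return line.point


def diaphysis_axis_2d(slice_, label_code: int = 4) -> Line2D:
    """Humeral diaphysis axis on a slice: the vertical (+y) line through
    the centroid of the diaphysis label.

    The slice frame construction guarantees the in-plane y axis is
    parallel to the projected diaphysis axis, so only the centroid is
    estimated from the image.
    """
    from .reslice import PlanarSlice  # local import to avoid a cycle

    if not isinstance(slice_, PlanarSlice):
        raise TypeError("diaphysis_axis_2d expects a PlanarSlice")
    mask = slice_.image == label_code
    if not mask.any():
        raise GeometryError("no diaphysis pixels in slice")
    ij = np.argwhere(mask).mean(axis=0)
    centroid = slice_.pixel_to_plane(ij[None, :])[0]
    return Line2D(point=centroid, direction=np.array([0.0, 1.0]))


def build_wrap(
    dip2d,
    pip2d,
    circle: Circle,
    axis: Line2D | None = None,
    side: str = "left",
) -> TangentConstruction:
    """Construct the taut string path DIP -> pulley -> PIP on a slice.

    ``side='left'`` wraps the lateral aspect (right-shoulder convention,
    +x lateral): traveling proximally along the MD line the circle center
    lies to the left; the proximal tangent is taken on the complementary
    side so the two tangents share the same wrap arc.

    Raises GeometryError if either insertion lies inside the circle or
    if the straight chord DIP-PIP clears the circle (no wrap: the string
    would not deflect and the pulley model does not apply).
    """
    dip2d = np.asarray(dip2d, dtype=float)
    pip2d = np.asarray(pip2d, dtype=float)
    center, rho = np.asarray(circle[0], dtype=float), float(circle[1])
    if axis is None:
        axis = Line2D(point=np.zeros(2), direction=np.array([0.0, 1.0]))

    chord = pip2d - dip2d
    chord_len = np.linalg.norm(chord)
    if chord_len == 0:
        raise GeometryError("DIP and PIP coincide")
    u = chord / chord_len
    w = center - dip2d
    t = float(np.clip(w @ u, 0.0, chord_len))
    chord_dist = float(np.linalg.norm(w - t * u))
    if chord_dist >= rho:
        raise GeometryError(
            f"string DIP-PIP clears the pulley (chord distance {chord_dist:.3f} mm "
            f">= rho {rho:.3f} mm): no wrap"
        )

    md_line = tangent_from_point(dip2d, (center, rho), side=side)
    opposite = "right" if side == "left" else "left"
    prox_tan = tangent_from_point(pip2d, (center, rho), side=opposite)
    # Orient the proximal line along the fiber travel (contact -> PIP).
    proximal_line = Line2D(point=prox_tan.point, direction=-prox_tan.direction)
    return TangentConstruction(
        md_line=md_line,
        proximal_line=proximal_line,
        diaphysis_axis=axis,
        contact_md=md_line.point,
        contact_prox=prox_tan.point,
        dip2d=dip2d,
        pip2d=pip2d,
    )


def measure_angles(construction: TangentConstruction) -> AngleSet:
    """Angles E, B, T (degrees) from a tangent construction.

    E is the unsigned acute angle between the MD line and the diaphysis
    axis.  B is the angle formed at the intersection of the MD line and
    the proximal line, measured between the two fiber segments leaving
    the pulley (toward the distal and the proximal insertion): for a
    string wrapping an arc alpha, B = 180 - alpha.  This is the angle
    consistent with the axial force balance
    Ry = F1 cos(E) + F1 cos(2T + E), with T = B/2: a straight string
    (no wrap) has B = 180 and exerts no radial reaction, while a string
    folded fully around the pulley has B = 0 and the maximal reaction.
    """
    v1 = construction.md_line.direction
    v2 = construction.proximal_line.direction
    ay = construction.diaphysis_axis.direction
    cos_turn = float(np.clip(v1 @ v2, -1.0, 1.0))
    turn = float(np.degrees(np.arccos(cos_turn)))  # wrap arc
    B = 180.0 - turn
    if B <= 1e-12 or B >= 180 - 1e-12:
        raise GeometryError("MD and proximal lines are parallel: no pulley deflection")
    E = float(np.degrees(np.arccos(np.clip(abs(v1 @ ay), 0.0, 1.0))))
    return AngleSet(E=E, B=B)
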