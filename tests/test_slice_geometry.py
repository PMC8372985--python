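"""Tangent construction and angle measurement on a slice."""

import math

import numpy as np
import pytest

from rsadeltoid.reslice import PlaneFrame, resample
from rsadeltoid.slicegeom import (
    build_wrap,
    diaphysis_axis_2d,
    measure_angles,
    tangent_from_point,
)
from rsadeltoid.types import GeometryError, Line2D, TangentConstruction

CIRCLE = (np.zeros(2), 30.0)


def brute_force_tangent(p, circle, side):
    """Oracle: scan a million directions, keep those whose line through p
    has distance to the center closest to rho, then pick the requested
    side."""
    center, rho = np.asarray(circle[0]), circle[1]
    angles = np.linspace(0, 2 * np.pi, 1_000_000, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    m = center - p
    cross = dirs[:, 0] * m[1] - dirs[:, 1] * m[0]
    err = np.abs(np.abs(cross) - rho)
    wanted = cross > 0 if side == "left" else cross < 0
    # tangent directions point toward the contact (forward half-plane)
    forward = dirs @ m > 0
    idx = np.where(wanted & forward)[0]
    best = idx[np.argmin(err[idx])]
    return dirs[best]


class TestTangentFromPoint:
    def test_half_angle_at_double_radius(self):
        p = np.array([-60.0, 0.0])
        line = tangent_from_point(p, CIRCLE, side="left")
        to_center = -p / np.linalg.norm(p)
        ang = math.degrees(math.acos(np.clip(line.direction @ to_center, -1, 1)))
        assert ang == pytest.approx(30.0, abs=1e-9)  # asin(1/2)

    def test_tangency(self):
        p = np.array([5.0, -80.0])
        for side in ("left", "right"):
            line = tangent_from_point(p, CIRCLE, side=side)
            assert line.distance_to(CIRCLE[0]) == pytest.approx(30.0, abs=1e-9)
            assert np.linalg.norm(line.point) == pytest.approx(30.0, abs=1e-9)

    @pytest.mark.parametrize("p", [(5.0, -80.0), (-40.0, 30.0), (60.0, 10.0)])
    @pytest.mark.parametrize("side", ["left", "right"])
    def test_matches_brute_force_direction_scan(self, p, side):
        p = np.asarray(p, dtype=float)
        line = tangent_from_point(p, CIRCLE, side=side)
        oracle = brute_force_tangent(p, CIRCLE, side)
        ang = math.degrees(
            math.acos(np.clip(line.direction @ oracle, -1.0, 1.0))
        )
        assert ang < 0.01

    def test_point_on_or_inside_circle_raises(self):
        with pytest.raises(GeometryError, match="inside or on"):
            tangent_from_point(np.array([30.0, 0.0]), CIRCLE)
        with pytest.raises(GeometryError, match="inside or on"):
            tangent_from_point(np.array([10.0, 5.0]), CIRCLE)


class TestBuildWrap:
    DIP = np.array([5.0, -80.0])
    PIP = np.array([-40.0, 30.0])

    def test_lines_are_tangent_and_contacts_on_circle(self):
        con = build_wrap(self.DIP, self.PIP, CIRCLE)
        for line in (con.md_line, con.proximal_line):
            assert line.distance_to(CIRCLE[0]) == pytest.approx(30.0, abs=1e-6)
        for c in (con.contact_md, con.contact_prox):
            assert np.linalg.norm(c - CIRCLE[0]) == pytest.approx(30.0, abs=1e-6)

    def test_angles_match_brute_force_tangents(self):
        """Angles from the closed-form construction equal those from the
        brute-force direction scan to better than 0.01 degrees."""
        con = build_wrap(self.DIP, self.PIP, CIRCLE)
        ang = measure_angles(con)
        v1 = brute_force_tangent(self.DIP, CIRCLE, "left")
        u2 = brute_force_tangent(self.PIP, CIRCLE, "right")
        v2 = -u2
        B = 180.0 - math.degrees(math.acos(np.clip(v1 @ v2, -1, 1)))
        E = math.degrees(math.acos(abs(v1[1])))
        assert ang.B == pytest.approx(B, abs=0.01)
        assert ang.E == pytest.approx(E, abs=0.01)
        assert ang.T == pytest.approx(ang.B / 2, abs=1e-12)

    def test_B_is_supplement_of_wrap_arc(self):
        """The angle at the line intersection is the supplement of the
        arc subtended between the two contact points: a longer wrap
        means a smaller B (and larger radial reaction)."""
        con = build_wrap(self.DIP, self.PIP, CIRCLE)
        ang = measure_angles(con)
        a1 = math.atan2(con.contact_md[1], con.contact_md[0])
        a2 = math.atan2(con.contact_prox[1], con.contact_prox[0])
        arc = math.degrees((a2 - a1) % (2 * math.pi))
        assert ang.B == pytest.approx(180.0 - arc, abs=1e-9)

    def test_string_clearing_pulley_raises(self):
        with pytest.raises(GeometryError, match="no wrap"):
            build_wrap(np.array([60.0, -80.0]), np.array([60.0, 80.0]), CIRCLE)

    def test_insertion_inside_pulley_raises(self):
        with pytest.raises(GeometryError):
            build_wrap(np.array([5.0, -10.0]), self.PIP, CIRCLE)

    def test_mirror_symmetry(self):
        """Reflecting the slice about the diaphysis axis leaves E, B, T
        unchanged (with the wrap side mirrored)."""
        con = build_wrap(self.DIP, self.PIP, CIRCLE)
        mirror = build_wrap(
            self.DIP * [-1, 1], self.PIP * [-1, 1], CIRCLE, side="right"
        )
        a, b = measure_angles(con), measure_angles(mirror)
        assert a.E == pytest.approx(b.E, abs=1e-9)
        assert a.B == pytest.approx(b.B, abs=1e-9)

    def test_scale_invariance(self):
        con = build_wrap(self.DIP, self.PIP, CIRCLE)
        scaled = build_wrap(3 * self.DIP, 3 * self.PIP, (np.zeros(2), 90.0))
        a, b = measure_angles(con), measure_angles(scaled)
        assert a.E == pytest.approx(b.E, abs=1e-9)
        assert a.B == pytest.approx(b.B, abs=1e-9)


class TestMeasureAngles:
    def test_md_parallel_to_axis_gives_zero_E(self):
        con = TangentConstruction(
            md_line=Line2D(np.array([30.0, 0.0]), np.array([0.0, 1.0])),
            proximal_line=Line2D(np.array([0.0, 30.0]), np.array([-1.0, 0.0])),
            diaphysis_axis=Line2D(np.zeros(2), np.array([0.0, 1.0])),
            contact_md=np.array([30.0, 0.0]),
            contact_prox=np.array([0.0, 30.0]),
            dip2d=np.array([30.0, -100.0]),
            pip2d=np.array([-50.0, 30.0]),
        )
        ang = measure_angles(con)
        assert ang.E == pytest.approx(0.0, abs=1e-12)
        assert ang.B == pytest.approx(90.0, abs=1e-12)

    def test_parallel_lines_raise(self):
        con = TangentConstruction(
            md_line=Line2D(np.array([30.0, 0.0]), np.array([0.0, 1.0])),
            proximal_line=Line2D(np.array([-30.0, 0.0]), np.array([0.0, 1.0])),
            diaphysis_axis=Line2D(np.zeros(2), np.array([0.0, 1.0])),
            contact_md=np.array([30.0, 0.0]),
            contact_prox=np.array([-30.0, 0.0]),
            dip2d=np.array([30.0, -100.0]),
            pip2d=np.array([-30.0, 100.0]),
        )
        with pytest.raises(GeometryError, match="parallel"):
            measure_angles(con)


class TestDiaphysisAxis2D:
    def make_slice(self, labels):
        frame = PlaneFrame(
            origin=np.zeros(3), basis=np.eye(3), pixel_spacing=1.0,
            extent=float(labels.shape[0] - 1),
        )
        from rsadeltoid.reslice import PlanarSlice

        return PlanarSlice(
            image=labels, intensity=labels.astype(float), frame=frame
        )

    def test_vertical_shaft_centroid_and_direction(self):
        labels = np.zeros((21, 21), dtype=np.uint8)
        labels[9:12, :] = 4
        sl = self.make_slice(labels)
        axis = diaphysis_axis_2d(sl)
        assert np.allclose(axis.direction, [0, 1])
        assert axis.point[0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_label_raises(self):
        sl = self.make_slice(np.zeros((11, 11), dtype=np.uint8))
        with pytest.raises(GeometryError, match="diaphysis"):
            diaphysis_axis_2d(sl)


def test_pipeline_angles_on_resampled_slice(reference_params, reference_truth):
    """Measuring on an actually resampled slice image: the diaphysis axis
    recovered from the label image matches the frame's y axis, and the
    wrap angles from the slice circle equal the analytic ground truth."""
    from rsadeltoid import synthetic
    from rsadeltoid.reslice import plane_from_three_points, slice_circle
    from rsadeltoid.types import Sphere
    from dataclasses import replace

    params = replace(reference_params, voxel_spacing=np.array([2.0, 2.0, 3.0]))
    volume = synthetic.voxelize(params)
    site = params.insertion_sites[1]  # M1 -> S2
    frame = plane_from_three_points(
        params.acromial_center, site.position, params.diaphysis_center,
        axis_direction=params.diaphysis_axis, pixel_spacing=1.0,
    )
    sl = resample(volume, frame)
    axis = diaphysis_axis_2d(sl)
    assert np.allclose(axis.direction, [0, 1])
    # centroid of the rasterized shaft lies on the true axis within a voxel
    true_axis_x = frame.world_to_plane(params.diaphysis_center)[0][0]
    assert abs(axis.point[0] - true_axis_x) < 2.0

    circle = slice_circle(Sphere(params.implant_center, params.implant_radius), frame)
    con = build_wrap(
        frame.world_to_plane(params.distal_insertion)[0],
        frame.world_to_plane(site.position)[0],
        circle,
        axis=axis,
    )
    ang = measure_angles(con)
    ref = reference_truth.angles("S2", 0.0)
    assert ang.E == pytest.approx(ref.E, abs=1e-6)
    assert ang.B == pytest.approx(ref.B, abs=1e-6)
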