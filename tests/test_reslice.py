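"""Plane construction, volume resampling and sphere-plane intersection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsadeltoid.reslice import (
    AcromialArc,
    PlaneFrame,
    arc_candidates,
    cubic_weight,
    insertion_points,
    plane_from_three_points,
    resample,
    slice_circle,
)
from rsadeltoid.types import GeometryError, LabeledVolume, Sphere


def simple_volume(labels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return LabeledVolume(voxels=labels, spacing=np.asarray(spacing), affine=affine)


class TestAcromialArc:
    def test_candidate_count_on_half_circle(self):
        arc = AcromialArc(center=np.zeros(3), radius=25, start_deg=-90, span_deg=180)
        assert len(arc_candidates(arc, 10)) == 19

    def test_zero_step_raises(self):
        arc = AcromialArc(center=np.zeros(3), radius=25, start_deg=0, span_deg=90)
        with pytest.raises(GeometryError, match="step"):
            arc_candidates(arc, 0)

    def test_sites_labeled_in_arc_order(self):
        arc = AcromialArc(center=np.zeros(3), radius=25, start_deg=-75, span_deg=150)
        sites = insertion_points(arc, 10, site_indices=(0, 3, 9, 15))
        assert [s.label for s in sites] == ["P1", "M1", "A3", "A2"]
        assert [s.arc_index for s in sites] == [0, 3, 9, 15]
        zs = [s.position[2] for s in sites]
        assert all(a < b for a, b in zip(zs, zs[1:]))  # posterior -> anterior

    def test_arc_too_short_raises(self):
        arc = AcromialArc(center=np.zeros(3), radius=25, start_deg=0, span_deg=40)
        with pytest.raises(GeometryError, match="arc too short"):
            insertion_points(arc, 10, site_indices=(0, 1, 2, 10))
        short = AcromialArc(center=np.zeros(3), radius=25, start_deg=0, span_deg=20)
        with pytest.raises(GeometryError, match="30 degrees"):
            insertion_points(short, 10, site_indices=(0, 1, 2, 3))


class TestPlaneFrame:
    def test_canonical_triple_gives_z_plane(self):
        f = plane_from_three_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert abs(abs(f.normal[2]) - 1.0) < 1e-12
        assert np.allclose(f.basis @ f.basis.T, np.eye(3), atol=1e-12)

    def test_defining_points_lie_in_plane(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p1, p2, p3 = rng.normal(scale=50, size=(3, 3))
            try:
                f = plane_from_three_points(p1, p2, p3)
            except GeometryError:
                continue
            for p in (p1, p2, p3):
                assert abs(float(f.plane_distance(p)[0])) < 1e-9

    def test_collinear_points_raise(self):
        with pytest.raises(GeometryError, match="collinear"):
            plane_from_three_points((0, 0, 0), (1, 1, 1), (2, 2, 2))

    def test_in_plane_y_parallel_to_projected_axis(self):
        axis = np.array([0.2, 0.9, 0.1])
        axis /= np.linalg.norm(axis)
        f = plane_from_three_points((0, 0, 0), (10, 3, 7), (-4, -20, 1), axis)
        proj = axis - (axis @ f.normal) * f.normal
        proj /= np.linalg.norm(proj)
        assert np.allclose(f.y_hat, proj, atol=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.normal(scale=30, size=(3, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        axis = np.array([0.0, 1.0, 0.0])
        f0 = plane_from_three_points(*p, axis)
        f1 = plane_from_three_points(*(pt @ q.T for pt in p), q @ axis)
        # world->plane coordinates of corresponding points agree up to the
        # lateral sign convention of the frame
        uv0 = f0.world_to_plane(p[1])
        uv1 = f1.world_to_plane(q @ p[1])
        assert abs(uv0[0, 1] - uv1[0, 1]) < 1e-9
        assert abs(abs(uv0[0, 0]) - abs(uv1[0, 0])) < 1e-9

    def test_frame_is_rigid(self):
        f = plane_from_three_points((0, 0, 4), (30, 5, -2), (-10, -40, 9))
        uv = np.array([[0.0, 0.0], [37.5, -12.25]])
        world = f.plane_to_world(uv)
        assert np.linalg.norm(world[1] - world[0]) == pytest.approx(
            np.linalg.norm(uv[1] - uv[0]), abs=1e-9
        )


class TestCubicKernel:
    def test_closed_form_values(self):
        assert cubic_weight(0.0) == pytest.approx(1.0)
        assert cubic_weight(0.5) == pytest.approx(0.5)
        assert cubic_weight(1.0) == pytest.approx(0.0)

    def test_partition_of_unity(self):
        t = np.linspace(0, 1, 11)
        assert np.allclose(cubic_weight(t) + cubic_weight(1 - t), 1.0, atol=1e-12)


class TestResample:
    def test_constant_volume_reproduced(self):
        vol = simple_volume(np.full((12, 12, 12), 3, dtype=np.uint8))
        f = plane_from_three_points((2, 2, 5.3), (8, 2, 5.3), (2, 8, 5.3),
                                    axis_direction=(0, 1, 0),
                                    pixel_spacing=0.5, extent=5.0)
        sl = resample(vol, f)
        inside = sl.intensity > 0
        assert inside.any()
        assert np.allclose(sl.intensity[inside], 3.0, atol=1e-12)
        assert (sl.image[inside] == 3).all()

    def test_plane_through_voxel_centers_is_exact(self):
        """An axis-aligned slice through voxel centers reproduces the
        label values exactly (kernel weight 1 at distance 0)."""
        labels = np.zeros((9, 9, 9), dtype=np.uint8)
        labels[::2, :, :] = 4
        vol = simple_volume(labels)
        f = PlaneFrame(
            origin=np.array([4.0, 4.0, 4.0]),
            basis=np.eye(3),
            pixel_spacing=1.0,
            extent=8.0,
        )
        sl = resample(vol, f)
        expected = labels[:, :, 4]
        np.testing.assert_array_equal(sl.image, expected)
        np.testing.assert_allclose(sl.intensity, expected.astype(float), atol=1e-12)

    def test_matches_direct_eight_corner_blend(self):
        """Oblique resampling agrees with an independent per-pixel
        evaluation of the eight-corner kernel blend."""
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 5, size=(10, 10, 10)).astype(np.uint8)
        vol = simple_volume(labels)
        f = plane_from_three_points(
            (2.2, 3.1, 4.7), (7.9, 4.2, 3.3), (3.5, 7.7, 6.1),
            pixel_spacing=1.0, extent=4.0,
        )
        sl = resample(vol, f)

        def w(t):
            t = min(abs(t), 1.0)
            return 2 * t**3 - 3 * t**2 + 1

        n = f.n_pixels
        for i in range(n):
            for j in range(n):
                uv = f.pixel_to_plane(np.array([[i, j]]))
                world = f.plane_to_world(uv)[0]
                idx = world  # identity affine
                base = np.floor(idx).astype(int)
                frac = idx - base
                num = den = 0.0
                for c in range(8):
                    offs = np.array([(c >> k) & 1 for k in range(3)])
                    ci = base + offs
                    if (ci < 0).any() or (ci >= 10).any():
                        continue
                    wt = w(frac[0] - offs[0]) * w(frac[1] - offs[1]) * w(frac[2] - offs[2])
                    num += wt * labels[tuple(ci)]
                    den += wt
                if den > 0:
                    assert sl.intensity[i, j] == pytest.approx(num / den, abs=1e-9)

    def test_plane_outside_volume_raises(self):
        vol = simple_volume(np.zeros((5, 5, 5), dtype=np.uint8))
        f = PlaneFrame(
            origin=np.array([500.0, 500.0, 500.0]), basis=np.eye(3),
            pixel_spacing=1.0, extent=4.0,
        )
        with pytest.raises(GeometryError, match="outside"):
            resample(vol, f)


class TestSliceCircle:
    def test_great_circle(self):
        f = PlaneFrame(origin=np.zeros(3), basis=np.eye(3))
        c, rho = slice_circle(Sphere(np.zeros(3), 30.0), f)
        assert rho == pytest.approx(30.0)
        assert np.allclose(c, 0)

    def test_half_radius_offset(self):
        f = PlaneFrame(origin=np.zeros(3), basis=np.eye(3))
        c, rho = slice_circle(Sphere(np.array([0.0, 0.0, 15.0]), 30.0), f)
        assert rho == pytest.approx(math.sqrt(900 - 225), abs=1e-12)

    def test_plane_missing_sphere_raises(self):
        f = PlaneFrame(origin=np.zeros(3), basis=np.eye(3))
        with pytest.raises(GeometryError, match="misses"):
            slice_circle(Sphere(np.array([0.0, 0.0, 31.0]), 30.0), f)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pythagoras_identity(self, seed):
        rng = np.random.default_rng(seed)
        sphere = Sphere(rng.normal(scale=20, size=3), 5 + 30 * rng.random())
        pts = rng.normal(scale=30, size=(3, 3))
        try:
            f = plane_from_three_points(*pts)
            c2d, rho = slice_circle(sphere, f)
        except GeometryError:
            return
        d = float(f.plane_distance(sphere.cent)[0])
        assert rho**2 + d**2 == pytest.approx(sphere.r**2, rel=1e-9)
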