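"""Plane slicing, polygon metrics, rotated bounding rectangles, and the
section-series centreline against analytic circles/ellipses/hyperboloids."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from junctshape.cross_section import (
    SectionPlane,
    min_area_rect,
    polygon_area,
    section_series,
    select_loop,
    slice_plane,
)
from junctshape.mesh_model import SurfaceMesh
from junctshape.synthetic_data import SyntheticJunctionSpec, make_hourglass


def regular_polygon(r: float, n: int) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def rotate2d(pts: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return pts @ np.array([[c, -s], [s, c]]).T


class TestSlicePlane:
    def test_cylinder_section_is_circle(self, straight_cylinder):
        mesh, r = straight_cylinder
        loops = slice_plane(mesh, SectionPlane([0, 0, 30.0], [0, 0, 1]))
        closed = [lp for lp in loops if lp.closed]
        assert len(closed) == 1
        assert polygon_area(closed[0].points2d) == pytest.approx(
            np.pi * r**2, rel=1e-2
        )

    def test_torus_through_hole_gives_two_loops(self):
        torus = trimesh.creation.torus(major_radius=50.0, minor_radius=10.0)
        loops = slice_plane(
            SurfaceMesh.from_trimesh(torus), SectionPlane([0, 0, 0], [0, 0, 1])
        )
        assert sum(lp.closed for lp in loops) == 2

    def test_plane_missing_mesh_empty(self, straight_cylinder):
        mesh, _ = straight_cylinder
        assert slice_plane(mesh, SectionPlane([0, 0, 500.0], [0, 0, 1])) == []


class TestSelectLoop:
    def test_nearest_centroid_wins(self):
        torus = trimesh.creation.torus(major_radius=50.0, minor_radius=10.0)
        loops = slice_plane(
            SurfaceMesh.from_trimesh(torus), SectionPlane([0, 0, 0], [0, 0, 1])
        )
        lp = select_loop(loops, np.array([0.0, 0.0, 0.0]))
        # the inner circle (radius 40) is nearer the torus centre
        assert polygon_area(lp.points2d) == pytest.approx(
            np.pi * 40**2, rel=2e-2
        )

    def test_no_closed_loop_raises(self):
        with pytest.raises(ValueError, match="open section"):
            select_loop([], np.zeros(3))


class TestPolygonArea:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert polygon_area(sq) == pytest.approx(1.0)

    def test_fine_polygon_matches_circle(self):
        assert polygon_area(regular_polygon(10.0, 1024)) == pytest.approx(
            np.pi * 100, rel=1e-4
        )

    def test_orientation_independent(self):
        poly = regular_polygon(7.0, 33)
        assert polygon_area(poly) == pytest.approx(polygon_area(poly[::-1]))


class TestMinAreaRect:
    def test_axis_aligned_rectangle(self):
        rect = np.array([[0, 0], [20, 0], [20, 10], [0, 10]], dtype=float)
        major, minor, _ = min_area_rect(rect)
        assert (major, minor) == pytest.approx((20.0, 10.0), abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(angle=st.floats(0.0, np.pi, allow_nan=False))
    def test_rotation_invariant_sides(self, angle):
        rect = np.array([[0, 0], [20, 0], [20, 10], [0, 10]], dtype=float)
        major, minor, _ = min_area_rect(rotate2d(rect, angle))
        assert major == pytest.approx(20.0, abs=1e-6)
        assert minor == pytest.approx(10.0, abs=1e-6)

    def test_ellipse_bounding_box(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        ellipse = np.column_stack([10 * np.cos(t), 5 * np.sin(t)])
        major, minor, _ = min_area_rect(rotate2d(ellipse, 0.6))
        assert major == pytest.approx(20.0, rel=5e-3)
        assert minor == pytest.approx(10.0, rel=5e-3)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.linspace(0, 10, 5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            min_area_rect(line)

    def test_rect_bounds_area_for_convex_loops(self):
        for n in (8, 32, 128):
            loop = regular_polygon(9.0, n)
            major, minor, _ = min_area_rect(loop)
            area = polygon_area(loop)
            assert area <= major * minor + 1e-9
            assert major * minor <= 4 * area

    def test_point_density_stable(self):
        sides = [min_area_rect(regular_polygon(10.0, n))[:2] for n in (64, 256, 1024)]
        ref = np.asarray(sides[-1])
        for s in sides[:-1]:
            np.testing.assert_allclose(np.asarray(s), ref, rtol=5e-3)


class TestSectionSeries:
    def test_cylinder_constant_areas(self, straight_cylinder):
        mesh, r = straight_cylinder
        secs = section_series(
            mesh, [0, 0, 0.5], [0, 0, 1], step=1.0, range_nm=50, mode="fixed"
        )
        areas = np.array([c.area for c in secs])
        assert np.ptp(areas) / areas.mean() < 1e-2

    def test_hyperboloid_minimum_at_waist(self):
        spec = SyntheticJunctionSpec(neck_diameter=20.0, neck_scale=10.0)
        mesh, truth = make_hourglass(spec)
        secs = section_series(
            mesh, [0, 0, 0], [0, 0, 1], step=0.5, range_nm=30, mode="fixed"
        )
        areas = np.array([c.area for c in secs])
        stations = np.array([c.station_s for c in secs])
        s_min = stations[np.argmin(areas)]
        assert abs(s_min - truth.true_neck_station) <= 0.5
        assert areas.min() == pytest.approx(np.pi * 100, rel=1e-2)

    def test_adaptive_tracks_elbow_where_fixed_fails(self, elbow_tube):
        mesh, r = elbow_tube
        expected = np.pi * r**2
        adaptive = section_series(
            mesh, [0, 0, 0.5], [0, 0, 1], step=0.5, range_nm=40,
            mode="adaptive", min_range=10,
        )
        a = np.array([c.area for c in adaptive])
        assert np.abs(a - expected).max() / expected < 0.05
        fixed = section_series(
            mesh, [0, 0, 0.5], [0, 0, 1], step=0.5, range_nm=40,
            mode="fixed", min_range=10,
        )
        f = np.array([c.area for c in fixed])
        assert np.abs(f - expected).max() / expected > 0.05

    def test_deterministic(self, straight_cylinder):
        mesh, _ = straight_cylinder
        runs = [
            section_series(mesh, [0, 0, 0.5], [0, 0, 1], step=1.0,
                           range_nm=20, mode="adaptive")
            for _ in range(2)
        ]
        for c0, c1 in zip(*runs):
            assert c0.area == c1.area
            np.testing.assert_array_equal(c0.loop, c1.loop)

    def test_lost_section_before_min_range_raises(self, straight_cylinder):
        mesh, _ = straight_cylinder  # length 60: stations past it vanish
        with pytest.raises(ValueError, match="lost section"):
            section_series(mesh, [0, 0, 0.5], [0, 0, 1], step=2.0,
                           range_nm=100, mode="fixed", min_range=100)

    def test_invalid_step_rejected(self, straight_cylinder):
        mesh, _ = straight_cylinder
        with pytest.raises(ValueError, match="step"):
            section_series(mesh, [0, 0, 0], [0, 0, 1], step=6.0, range_nm=10)
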