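"""Neck detection, width/aspect-ratio/length metrics, shrinkage correction,
and the auxiliary 2-point measurements, validated against the hyperboloid
closed forms and brute-force oracles."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from junctshape.cross_section import section_series
from junctshape.junction_morphometry import (
    JunctionAnnotation,
    LumenClass,
    correct_shrinkage,
    distance_to_surface,
    find_neck,
    is_constricted,
    junction_aspect_ratio,
    junction_length,
    junction_width,
    measure_junction,
    ne_width_below_junction,
    side_profile,
    two_point_width,
)
from junctshape.mesh_model import SurfaceMesh
from junctshape.synthetic_data import (
    SyntheticJunctionSpec,
    make_hourglass,
    make_wide_cone,
)

Z = np.array([0.0, 0.0, 1.0])


def hourglass_sections(neck_diameter=20.0, neck_scale=10.0, **kw):
    spec = SyntheticJunctionSpec(
        neck_diameter=neck_diameter, neck_scale=neck_scale, **kw
    )
    mesh, truth = make_hourglass(spec)
    secs = section_series(mesh, [0, 0, 0], Z, step=0.5, range_nm=30, mode="fixed")
    return mesh, truth, secs


def brute_force_length(r0: float, c: float, factor: float = 1.2) -> float:
    """Independent oracle: scan the analytic area profile at 0.1 nm pitch for
    the first stations (each side of the waist) with >= factor-fold area."""
    s = np.arange(0.0, 3 * c, 0.01)
    area = np.pi * r0**2 * (1 + (s / c) ** 2)
    thresh = factor * np.pi * r0**2
    s_cross = s[np.argmax(area >= thresh)]
    return 2 * s_cross


class TestFindNeck:
    def test_hyperboloid_neck_at_waist(self):
        _, truth, secs = hourglass_sections()
        neck = find_neck(secs, window=25.0)
        assert abs(neck.station_s - truth.true_neck_station) <= 0.5
        assert neck.area == pytest.approx(np.pi * 100, rel=1e-2)
        assert is_constricted(secs)

    def test_wide_cone_not_constricted(self):
        spec = SyntheticJunctionSpec(
            neck_diameter=60.0, shape_class="wide_cone", neck_scale=30.0
        )
        mesh, _ = make_wide_cone(spec)
        secs = section_series(mesh, [0, 0, 0], Z, step=0.5, range_nm=25, mode="fixed")
        assert not is_constricted(secs)
        assert find_neck(secs).station_s == secs[0].station_s

    def test_tie_goes_to_earlier_station(self):
        from junctshape.cross_section import CrossSection

        def fake(s, area):
            loop = np.array([[0, 0], [3, 0], [3, 3], [0, 3]], dtype=float)
            return CrossSection(s, loop, area, 3.0, 3.0, 0.0, np.zeros(3))

        secs = [fake(0.0, 5.0), fake(5.0, 2.0), fake(10.0, 2.0), fake(15.0, 4.0)]
        assert find_neck(secs).station_s == 5.0

    def test_too_few_sections_rejected(self):
        _, _, secs = hourglass_sections()
        with pytest.raises(ValueError, match="sections"):
            find_neck(secs[:1])


class TestWidthAndAspectRatio:
    def test_circular_neck(self):
        _, _, secs = hourglass_sections(neck_diameter=20.0)
        neck = find_neck(secs)
        assert junction_width(neck) == pytest.approx(20.0, abs=0.4)
        assert junction_aspect_ratio(neck) == pytest.approx(1.0, abs=0.01)

    def test_elliptical_neck_mean_of_sides(self):
        _, truth, secs = hourglass_sections(neck_diameter=10.0, ellipticity=2.0)
        neck = find_neck(secs)
        assert truth.true_width == pytest.approx(15.0)
        assert junction_width(neck) == pytest.approx(15.0, rel=0.02)
        assert junction_aspect_ratio(neck) == pytest.approx(2.0, rel=0.02)

    def test_rigid_motion_invariance(self):
        spec = SyntheticJunctionSpec(neck_diameter=14.0, ellipticity=1.5)
        mesh, _ = make_hourglass(spec)
        ann = JunctionAnnotation("j", [0, 0, 0], Z)
        ref = measure_junction(mesh, ann, mode="fixed")
        rot = trimesh.transformations.rotation_matrix(0.9, [1, 2, 0.5])
        tm = mesh.to_trimesh()
        tm.apply_transform(rot)
        tm.apply_translation([40.0, -20.0, 11.0])
        base = (rot[:3, :3] @ np.zeros(3)) + [40.0, -20.0, 11.0]
        axis = rot[:3, :3] @ Z
        moved = measure_junction(
            SurfaceMesh.from_trimesh(tm),
            JunctionAnnotation("j", base, axis),
            mode="fixed",
        )
        assert moved.width_W == pytest.approx(ref.width_W, rel=1e-3)
        assert moved.aspect_ratio_AR == pytest.approx(ref.aspect_ratio_AR, rel=1e-3)
        assert moved.length_L == pytest.approx(ref.length_L, abs=0.51)

    def test_width_monotone_in_neck_diameter(self):
        widths = []
        for d in (7, 10, 14, 18, 24):
            spec = SyntheticJunctionSpec(neck_diameter=float(d))
            mesh, _ = make_hourglass(spec)
            res = measure_junction(
                mesh, JunctionAnnotation("j", [0, 0, 0], Z), mode="fixed"
            )
            widths.append(res.width_W)
        assert all(b > a for a, b in zip(widths, widths[1:]))


class TestJunctionLength:
    def test_hyperboloid_closed_form_and_brute_force(self):
        _, truth, secs = hourglass_sections(neck_diameter=20.0, neck_scale=10.0)
        neck = find_neck(secs)
        L, L1, L2, flags = junction_length(secs, neck)
        oracle = brute_force_length(10.0, 10.0)
        assert oracle == pytest.approx(2 * 10 * np.sqrt(0.2), abs=0.02)
        assert L == pytest.approx(oracle, abs=0.51)
        assert L == pytest.approx(L1 + L2)
        assert not flags

    def test_factor_near_one_gives_tiny_length(self):
        _, _, secs = hourglass_sections()
        neck = find_neck(secs)
        L, _, _, _ = junction_length(secs, neck, factor=1.0 + 1e-4)
        assert L is not None and L <= 1.1  # one station each side

    def test_factor_not_above_one_rejected(self):
        _, _, secs = hourglass_sections()
        with pytest.raises(ValueError, match="factor"):
            junction_length(secs, find_neck(secs), factor=1.0)

    def test_er_side_clipped_flags_truncated(self):
        # clip the ER side before the 1.2-fold area is reached: c*sqrt(0.2)=4.47
        spec = SyntheticJunctionSpec(
            neck_diameter=20.0, neck_scale=10.0, truncate_at=3.0
        )
        mesh, _ = make_hourglass(spec)
        res = measure_junction(
            mesh, JunctionAnnotation("j", [0, 0, 0], Z), mode="fixed",
        )
        assert "truncated_L2" in res.flags
        assert res.length_L is None
        assert res.L1 is not None


class TestShrinkageCorrection:
    @pytest.mark.parametrize(
        "measured,expected_native",
        [(7, 8), (20, 24), (4, 5), (15, 18)],
    )
    def test_measured_range_maps_to_native_range(self, measured, expected_native):
        assert round(correct_shrinkage(measured, 0.17)) == expected_native

    def test_zero_is_fixed_point(self):
        assert correct_shrinkage(0.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0, 100, allow_nan=False),
        b=st.floats(0, 100, allow_nan=False),
    )
    def test_linearity(self, a, b):
        assert correct_shrinkage(a + b) == pytest.approx(
            correct_shrinkage(a) + correct_shrinkage(b)
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            correct_shrinkage(10.0, 1.0)


class TestAuxiliaryMeasurements:
    def test_two_point_width(self):
        assert two_point_width([0, 0, 0], [0, 0, 20]) == pytest.approx(20.0)
        with pytest.raises(ValueError, match="coincide"):
            two_point_width([1, 2, 3], [1, 2, 3])

    def test_side_profile_gap_equals_neck_diameter(self):
        spec = SyntheticJunctionSpec(neck_diameter=20.0, neck_scale=10.0)
        mesh, truth = make_hourglass(spec)
        left, right = side_profile(mesh, [0, 0, truth.true_neck_station], Z)
        # minimum horizontal gap between the two traces is the neck diameter
        gap = right[:, 0].min() - left[:, 0].max()
        assert gap == pytest.approx(20.0, rel=0.02)
        # re-slice at 90 degrees: same gap for a circular neck
        left2, right2 = side_profile(
            mesh, [0, 0, truth.true_neck_station], Z, view_normal=[1, 0, 0]
        )
        gap2 = right2[:, 0].min() - left2[:, 0].max()
        assert gap2 == pytest.approx(gap, rel=0.01)

    def test_side_profile_cylinder_parallel_lines(self, straight_cylinder):
        mesh, r = straight_cylinder
        left, right = side_profile(mesh, [0, 0, 30.0], Z)
        assert np.allclose(left[:, 0], -r, atol=0.1)
        assert np.allclose(right[:, 0], r, atol=0.1)

    def test_ne_width_below_junction_flat_membranes(self):
        # flat INM 40 nm below the ONM plane (z=0)
        inm = SurfaceMesh(
            vertices=[[-1000, -1000, -40], [1000, -1000, -40],
                      [1000, 1000, -40], [-1000, 1000, -40]],
            faces=[[0, 1, 2], [0, 2, 3]],
        )
        w, controls = ne_width_below_junction([0, 0, 0], inm, [1, 0, 0])
        assert w == pytest.approx(40.0)
        assert controls == pytest.approx([40.0, 40.0])

    def test_ne_width_detects_local_dilation(self):
        # INM dips to -55 nm under the junction, -40 nm elsewhere
        x = np.linspace(-600, 600, 121)
        y = np.array([-600.0, 600.0])
        xx, yy = np.meshgrid(x, y, indexing="ij")
        zz = -40.0 - 15.0 * np.exp(-(xx**2) / (2 * 50.0**2))
        verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        faces = []
        for i in range(len(x) - 1):
            a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
            faces += [[a, b, c], [b, d, c]]
        inm = SurfaceMesh(verts, np.asarray(faces))
        w, controls = ne_width_below_junction([0, 0, 0], inm, [1, 0, 0])
        assert w > max(controls)
        assert w == pytest.approx(55.0, rel=0.02)

    def test_missing_inm_rejected(self):
        with pytest.raises(ValueError, match="INM"):
            ne_width_below_junction([0, 0, 0], None, [1, 0, 0])

    def test_distance_to_surface_against_brute_force(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=50.0)
        mesh = SurfaceMesh.from_trimesh(sphere)
        point = np.array([10.0, -20.0, 80.0])

        def brute(p):  # min distance over all triangles via dense sampling
            tri = sphere.triangles
            best = np.inf
            for a, b, c in tri:
                u = np.linspace(0, 1, 12)
                for s in u:
                    for t in u:
                        if s + t <= 1:
                            q = a + s * (b - a) + t * (c - a)
                            best = min(best, np.linalg.norm(q - p))
            return best

        assert distance_to_surface(point, mesh) == pytest.approx(
            brute(point), abs=0.05
        )

    def test_distance_zero_on_vertex(self):
        sphere = trimesh.creation.icosphere(subdivisions=1, radius=50.0)
        mesh = SurfaceMesh.from_trimesh(sphere)
        assert distance_to_surface(mesh.vertices[0], mesh) == pytest.approx(0.0, abs=1e-9)

    def test_plane_distance(self):
        plane = SurfaceMesh(
            vertices=[[-100, -100, 0], [100, -100, 0], [100, 100, 0], [-100, 100, 0]],
            faces=[[0, 1, 2], [0, 2, 3]],
        )
        assert distance_to_surface([0, 0, 50], plane) == pytest.approx(50.0)


class TestMeasureJunction:
    def test_contact_site_excluded(self):
        spec = SyntheticJunctionSpec(neck_diameter=20.0)
        mesh, _ = make_hourglass(spec)
        ann = JunctionAnnotation(
            "cs", [0, 0, 0], Z, lumen_class=LumenClass.CONTACT_SITE
        )
        with pytest.raises(ValueError, match="contact site"):
            measure_junction(mesh, ann)

    def test_full_pipeline_recovery_across_diameters(self):
        for d in (7.0, 12.0, 17.0, 24.0):
            spec = SyntheticJunctionSpec(neck_diameter=d, mesh_step=0.4)
            mesh, truth = make_hourglass(spec)
            # fine section step: the nearest-station rule quantizes L upward
            # by up to one step per side
            res = measure_junction(
                mesh, JunctionAnnotation("j", [0, 0, 0], Z), step=0.25,
                mode="fixed",
            )
            assert abs(res.width_W - truth.true_width) / truth.true_width < 0.02
            assert abs(res.length_L - truth.true_length) / truth.true_length < 0.06
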