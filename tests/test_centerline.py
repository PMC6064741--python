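import warnings

import numpy as np
import pytest

from neuritemorph import (
    Centerline,
    PointSet,
    SurfaceMesh,
    cross_sections,
    export_profile,
    fallback_centerline,
    load_centerline,
    max_radius,
    project_faces,
    project_points,
    surface_area,
    fixtures,
)
from neuritemorph.centerline_analysis import CrossSection, read_profile
from neuritemorph.mesh_core import write_obj


class TestLoadCenterline:
    def test_straight_segment_uniform_spacing(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.linspace(0, 10, 5)])
        cl = load_centerline(pts, n_vertices=101)
        np.testing.assert_allclose(cl.spacing(), 0.1, atol=1e-12)
        assert cl.arc_length[0] == 0.0

    def test_semicircle_arc_length(self):
        R = 3.0
        theta = np.linspace(0, np.pi, 500)
        pts = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                               np.zeros_like(theta)])
        cl = load_centerline(pts, n_vertices=50)
        assert cl.length == pytest.approx(np.pi * R, rel=0.005)

    def test_branching_obj_rejected(self, tmp_path):
        path = tmp_path / "y.obj"
        path.write_text(
            "o y\nv 0 0 0\nv 0 0 1\nv 1 0 2\nv -1 0 2\nl 1 2\nl 2 3\nl 2 4\n"
        )
        with pytest.raises(ValueError, match="branching"):
            load_centerline(path)

    def test_obj_chain_is_reordered(self, tmp_path):
        # edges given out of order still yield one end-to-end chain
        path = tmp_path / "chain.obj"
        path.write_text(
            "o c\nv 0 0 0\nv 0 0 1\nv 0 0 2\nv 0 0 3\nl 3 4\nl 1 2\nl 2 3\n"
        )
        cl = load_centerline(path, n_vertices=31)
        assert cl.length == pytest.approx(3.0)

    def test_csv_min_radius_interpolated(self, tmp_path):
        path = tmp_path / "cl.csv"
        lines = ["x,y,z,min_radius"]
        for z in np.linspace(0, 10, 21):
            lines.append(f"0,0,{z},{0.1 + 0.01 * z}")
        path.write_text("\n".join(lines) + "\n")
        cl = load_centerline(path, n_vertices=50)
        assert cl.min_radius is not None
        np.testing.assert_allclose(cl.min_radius,
                                   0.1 + 0.01 * cl.vertices[:, 2], atol=1e-9)

    def test_update_clears_attributes(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        cl = Centerline(pts)
        cl.cross_section_area = np.ones(5)
        moved = cl.updated(pts + [1.0, 0, 0])
        assert moved.cross_section_area is None
        assert moved.length == pytest.approx(cl.length)


class TestFallbackCenterline:
    def test_straight_cylinder_axis_recovered(self, straight_tube):
        mesh, _, _ = straight_tube
        cl = fallback_centerline(mesh)
        off_axis = np.linalg.norm(cl.vertices[:, :2], axis=1)
        assert off_axis.max() <= 0.02 * 0.3
        assert cl.validate_inside(mesh).all()

    def test_s_curved_tube_stays_inside(self):
        spec = fixtures.TubeSpec(length=10, base_radius=0.3, curve="s",
                                 axial_samples=80, radial_samples=32)
        mesh, _, _ = fixtures.make_bulged_tube(spec)
        cl = fallback_centerline(mesh)
        assert cl.validate_inside(mesh).all()

    def test_sphere_rejected(self):
        sphere = fixtures.make_icosphere(radius=1.0, subdivisions=2)
        with pytest.raises(ValueError, match="skeletonizer"):
            fallback_centerline(sphere)


class TestCrossSections:
    def test_cylinder_flat_area_profile(self, straight_tube):
        mesh, cl_true, _ = straight_tube
        cl = load_centerline(cl_true.vertices, n_vertices=80)
        cross_sections(mesh, cl)
        areas = cl.cross_section_area
        assert np.all(areas > 0)
        assert areas.std() / areas.mean() < 0.02
        assert areas.mean() == pytest.approx(np.pi * 0.09, rel=0.02)

    def test_normals_unit_and_perpendicular(self, straight_tube):
        mesh, cl_true, _ = straight_tube
        cl = load_centerline(cl_true.vertices, n_vertices=40)
        secs = cross_sections(mesh, cl)
        for i in range(1, len(cl) - 1):
            n = secs[i].plane_normal
            chord = cl.vertices[i + 1] - cl.vertices[i - 1]
            chord /= np.linalg.norm(chord)
            assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)
            assert abs(abs(n @ chord) - 1.0) < 1e-9  # normal along local chord

    def test_small_plane_diameter_warns_truncated(self, straight_tube):
        # an elliptically wide axon with an intersection disc narrower than
        # its major axis: the loop leaves the disc and comes back truncated
        mesh, cl_true, _ = straight_tube
        wide = SurfaceMesh("wide", mesh.vertices * [2.0, 1.0, 1.0], mesh.faces)
        cl = load_centerline(cl_true.vertices, n_vertices=20)
        with pytest.warns(UserWarning, match="truncated"):
            secs = cross_sections(wide, cl, plane_diameter=0.9)
        assert any(s.truncated for s in secs)

    def test_hairpin_selects_loop_containing_vertex(self):
        spec = fixtures.TubeSpec(length=10, base_radius=0.25, curve="hairpin",
                                 bend_radius=0.8, axial_samples=140,
                                 radial_samples=32)
        mesh, cl_true, _ = fixtures.make_bulged_tube(spec)
        cl = load_centerline(cl_true.vertices, n_vertices=80)
        from neuritemorph.centerline_analysis import _slice_loops
        i = 15  # middle of the first arm: the plane cuts both arms
        loops, _ = _slice_loops(mesh, cl.vertices[i], cl.tangents()[i], 50.0)
        assert len(loops) == 2
        secs = cross_sections(mesh, cl)
        # the chosen polygon is the one around the owner vertex
        assert np.linalg.norm(secs[i].centroid - cl.vertices[i]) < 0.25
        assert secs[i].area == pytest.approx(np.pi * 0.25 ** 2, rel=0.03)

    def test_bulge_peak_location_and_area(self, bulged_tube):
        spec, mesh, cl_true, rfn = bulged_tube
        cl = load_centerline(cl_true.vertices, n_vertices=100)
        cross_sections(mesh, cl)
        areas = cl.cross_section_area
        peak = int(np.argmax(areas))
        assert abs(cl.arc_length[peak] - spec.bulge_center) <= cl.spacing().max()
        assert areas[peak] == pytest.approx(np.pi * 0.3 ** 2, rel=0.05)

    def test_vertex_outside_mesh_gives_empty_section(self, straight_tube):
        mesh, _, _ = straight_tube
        outside = np.column_stack([np.full(10, 5.0), np.zeros(10),
                                   np.linspace(4, 6, 10)])
        cl = Centerline(outside)
        with pytest.warns(UserWarning, match="no intersection"):
            secs = cross_sections(mesh, cl, plane_diameter=1.0)
        assert all(s.empty and s.area == 0.0 for s in secs)


class TestMaxRadius:
    def circle_section(self, r, n=64):
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        boundary = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                    np.zeros(n)])
        return CrossSection(0, np.zeros(3), np.array([0, 0, 1.0]), boundary,
                            area=np.pi * r ** 2)

    def test_circle(self):
        assert max_radius(self.circle_section(0.4)) == pytest.approx(0.4, rel=1e-6)

    def test_ellipse_returns_semi_major(self):
        phi = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        a, b = 0.5, 0.2
        boundary = np.column_stack([a * np.cos(phi), b * np.sin(phi),
                                    np.zeros_like(phi)])
        cs = CrossSection(0, np.zeros(3), np.array([0, 0, 1.0]), boundary)
        assert max_radius(cs) == pytest.approx(a, rel=1e-3)

    def test_c_shape_with_external_centroid(self):
        # three-quarter annulus: the boundary-vertex centroid lies off-center
        phi = np.linspace(0, 1.5 * np.pi, 80)
        outer = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        inner = outer[::-1] * 0.8
        cs = CrossSection(0, np.zeros(3), np.array([0, 0, 1.0]),
                          np.vstack([outer, inner]))
        value = max_radius(cs)  # no error, plain max vertex distance
        assert value > 0.9

    def test_disc_lower_bound(self, straight_tube):
        mesh, cl_true, _ = straight_tube
        cl = load_centerline(cl_true.vertices, n_vertices=30)
        secs = cross_sections(mesh, cl)
        for s in secs:
            assert s.max_radius >= np.sqrt(s.area / np.pi) - 1e-9


class TestProjections:
    def chain(self, n=11):
        return Centerline(np.column_stack([np.zeros(n), np.zeros(n),
                                           np.arange(float(n))]))

    def test_sphere_at_vertex(self):
        cl = self.chain()
        sphere = fixtures.make_icosphere(center=(0, 0, 4.0), radius=0.1,
                                         subdivisions=1)
        counts = project_points(cl, [sphere])
        assert counts[4] == 1 and counts.sum() == 1

    def test_count_conservation(self):
        cl = self.chain()
        pts = fixtures.scatter_vesicles((-1, -1, 0, 1, 1, 10), 100, seed=2)
        counts = project_points(cl, pts)
        assert counts.sum() == 100

    def test_tie_goes_to_lowest_index(self):
        cl = self.chain()
        counts = project_points(cl, PointSet(np.array([[0.3, 0, 3.5]])))
        assert counts[3] == 1 and counts[4] == 0

    def test_face_area_conservation(self, icosphere4):
        cl = self.chain()
        patch = SurfaceMesh("patch", icosphere4.vertices + [0, 0, 7.0],
                            icosphere4.faces[:50])
        sums = project_faces(cl, patch)
        assert sums.sum() == pytest.approx(surface_area(
            SurfaceMesh("p", patch.vertices, patch.faces)), rel=1e-12)

    def test_patches_at_opposite_ends(self):
        cl = self.chain()
        tri = np.array([[0, 1, 2]])
        near_start = SurfaceMesh("a", np.array([[0.2, 0, 0], [0.3, 0, 0],
                                                [0.25, 0.1, 0.0]]), tri)
        near_end = SurfaceMesh("b", np.array([[0.2, 0, 10], [0.3, 0, 10],
                                              [0.25, 0.1, 10.0]]), tri)
        sums = project_faces(cl, [near_start, near_end])
        assert sums[0] > 0 and sums[-1] > 0
        assert np.all(sums[1:-1] == 0)


class TestExport:
    def test_cylinder_profile_round_trip(self, tmp_path, straight_tube):
        mesh, cl_true, _ = straight_tube
        cl = load_centerline(cl_true.vertices, n_vertices=60)
        cross_sections(mesh, cl)
        project_points(cl, fixtures.scatter_vesicles(("tube", 10, 0.25), 50,
                                                     seed=9))
        path = tmp_path / "profile.csv"
        export_profile(cl, path)
        df = read_profile(path)
        assert len(df) == 60
        assert list(df.columns)[:6] == ["vertex_index", "x", "y", "z",
                                        "arc_length_um",
                                        "cross_section_area_um2"]
        np.testing.assert_allclose(df["arc_length_um"], cl.arc_length,
                                   atol=1e-9)
        areas = df["cross_section_area_um2"].to_numpy(float)
        assert areas.std() / areas.mean() < 0.02
        assert df["sphere_count"].sum() == 50

    def test_missing_attributes_emitted_empty(self, tmp_path):
        cl = Centerline(np.column_stack([np.zeros(5), np.zeros(5),
                                         np.arange(5.0)]))
        path = tmp_path / "bare.csv"
        export_profile(cl, path)
        df = read_profile(path)
        assert df["cross_section_area_um2"].isna().all()
        assert df["sphere_count"].isna().all()

    def test_obj_polyline_source_round_trip(self, tmp_path):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.linspace(0, 5, 6)])
        mesh = SurfaceMesh("cl", pts,
                           edges=np.column_stack([np.arange(5), np.arange(1, 6)]))
        path = tmp_path / "cl.obj"
        write_obj(mesh, path)
        cl = load_centerline(path, n_vertices=26)
        assert cl.length == pytest.approx(5.0)
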