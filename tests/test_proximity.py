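import numpy as np
import pytest

from neuritemorph import (
    PointSet,
    SurfaceMesh,
    distance_histogram,
    interacting_regions,
    point_to_surface,
    surface_area,
    fixtures,
)
from neuritemorph.proximity import write_interaction_report


class TestPointToSurface:
    def test_point_on_vertex_is_zero(self, unit_cube):
        records = point_to_surface(PointSet(unit_cube.vertices[:1]), unit_cube)
        assert records[0].distance == 0.0

    def test_height_above_fine_grid_bounded(self):
        plate, _ = fixtures.make_plate_pair(side=1.0, gap=1.0, grid=41)
        h = 0.12
        records = point_to_surface(PointSet(np.array([[0.5, 0.5, h]])), plate)
        spacing = 1.0 / 40
        assert h <= records[0].distance <= np.hypot(h, spacing * np.sqrt(2) / 2)

    def test_matches_brute_force(self, icosphere4):
        pts = fixtures.scatter_vesicles((-2, -2, -2, 2, 2, 2), 1000, seed=1)
        records = point_to_surface(pts, icosphere4)
        brute = np.linalg.norm(
            pts.points[:, None, :] - icosphere4.vertices[None, :, :], axis=2
        ).min(axis=1)
        np.testing.assert_allclose([r.distance for r in records], brute,
                                   atol=1e-12)

    def test_triangle_refinement_never_larger(self, icosphere4):
        pts = fixtures.scatter_vesicles((-2, -2, -2, 2, 2, 2), 50, seed=4)
        coarse = point_to_surface(pts, icosphere4)
        fine = point_to_surface(pts, icosphere4, refine_to_triangles=True)
        for c, f in zip(coarse, fine):
            assert f.distance <= c.distance + 1e-12

    def test_mesh_objects_reduced_to_centroids(self, icosphere4):
        vesicle = fixtures.make_icosphere(center=(2.0, 0, 0), radius=0.02,
                                          subdivisions=1, name="ves")
        (rec,) = point_to_surface([vesicle], icosphere4)
        assert rec.object_name == "ves"
        assert rec.distance == pytest.approx(1.0, abs=0.01)

    def test_empty_surface_rejected(self):
        empty = SurfaceMesh("e", np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            point_to_surface(PointSet(np.zeros((1, 3))), empty)


class TestHistogram:
    def test_empty(self):
        edges, counts = distance_histogram([])
        assert len(counts) == 0

    def test_hand_counted(self):
        edges, counts = distance_histogram([0.01, 0.04, 0.06], bin_width=0.05)
        np.testing.assert_array_equal(counts, [2, 1])
        np.testing.assert_allclose(edges, [0.0, 0.05, 0.10])

    def test_conservation(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 0.4, 300)
        _, counts = distance_histogram(d, bin_width=0.05)
        assert counts.sum() == 300

    def test_boundary_goes_to_upper_bin(self):
        _, counts = distance_histogram([0.05], bin_width=0.05)
        np.testing.assert_array_equal(counts, [0, 1])


def brute_force_selection(mesh1, mesh2, T):
    d = np.linalg.norm(
        mesh1.vertices[:, None, :] - mesh2.vertices[None, :, :], axis=2)
    return d.min(axis=1) <= T, d.min(axis=0) <= T


class TestInteractingRegions:
    def test_close_plates_one_full_pair(self):
        p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.03, grid=21)
        report, kids1, kids2 = interacting_regions(p1, p2, T=0.05)
        assert len(report.pairs) == 1
        pair = report.pairs[0]
        assert pair.region1_name == "plate1.001"
        assert pair.region2_name == "plate2.001"
        # full 1 µm² captured (gap < T reaches straight across)
        assert pair.area1 == pytest.approx(1.0)
        assert pair.area2 == pytest.approx(1.0)
        assert report.total_area1 == pytest.approx(pair.area1)
        assert report.total_area2 == pytest.approx(pair.area2)
        np.testing.assert_allclose(pair.pair_centroid, [0.5, 0.5, 0.015])

    def test_far_plates_empty_report(self):
        p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.08, grid=21)
        report, kids1, kids2 = interacting_regions(p1, p2, T=0.05)
        assert report.pairs == []
        assert report.total_area1 == 0.0
        assert kids1 == [] and kids2 == []

    def test_oblique_gap_loses_boundary_ring_only(self):
        # plate tilted so only part of it comes within T: captured area is
        # the analytic footprint minus at most one boundary ring
        p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.0, grid=41)
        tilt = p2.vertices.copy()
        tilt[:, 2] = 0.03 + 0.08 * tilt[:, 0]  # z from 0.03 to 0.11
        p2 = SurfaceMesh("plate2", tilt, p2.faces)
        report, _, _ = interacting_regions(p1, p2, T=0.05)
        x_max = (0.05 - 0.03) / 0.08  # where the gap passes T
        footprint = x_max * 1.0
        ring = 1.0 / 40
        assert len(report.pairs) == 1
        assert footprint - 2 * ring <= report.pairs[0].area1 <= footprint + 2 * ring

    def test_kdtree_equals_brute_force(self):
        a = fixtures.make_icosphere(center=(0, 0, 0), radius=0.5, subdivisions=3)
        b = fixtures.make_icosphere(center=(1.02, 0, 0), radius=0.5, subdivisions=3)
        assert a.n_vertices <= 2000 and b.n_vertices <= 2000
        T = 0.1
        sel1, sel2 = brute_force_selection(a, b, T)
        from scipy.spatial import cKDTree
        d12, _ = cKDTree(b.vertices).query(a.vertices, distance_upper_bound=T)
        d21, _ = cKDTree(a.vertices).query(b.vertices, distance_upper_bound=T)
        np.testing.assert_array_equal(np.isfinite(d12), sel1)
        np.testing.assert_array_equal(np.isfinite(d21), sel2)

    def test_double_counted_region_and_totals(self):
        # one large plate of object 1 faces two separated small plates merged
        # into object 2: the large region appears in two pairs, but the
        # non-overlapping total counts it once
        big, _ = fixtures.make_plate_pair(side=1.0, gap=1.0, grid=21)
        small_a, _ = fixtures.make_plate_pair(side=0.3, gap=1.0, grid=7)
        small_b, _ = fixtures.make_plate_pair(side=0.3, gap=1.0, grid=7)
        # 0.06 µm apart: more than T, so they stay two components, but
        # their capture footprints on the big plate merge into one region
        va = small_a.vertices + [0.05, 0.35, 0.03]
        vb = small_b.vertices + [0.41, 0.35, 0.03]
        two = SurfaceMesh("object2", np.vstack([va, vb]),
                          np.vstack([small_a.faces,
                                     small_b.faces + small_a.n_vertices]))
        big = SurfaceMesh("object1", big.vertices, big.faces)
        report, kids1, kids2 = interacting_regions(big, two, T=0.05)
        assert len(kids2) == 2
        assert len(report.pairs) == 2
        names1 = {p.region1_name for p in report.pairs}
        assert names1 == {"object1.001"}  # same region paired twice
        sum_area1 = sum(p.area1 for p in report.pairs)
        assert sum_area1 > report.total_area1  # double counting inflates
        assert sum_area1 == pytest.approx(2 * report.total_area1)
        sum_area2 = sum(p.area2 for p in report.pairs)
        assert sum_area2 == pytest.approx(report.total_area2)

    def test_monotone_in_threshold(self):
        p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.0, grid=31)
        tilt = p2.vertices.copy()
        tilt[:, 2] = 0.02 + 0.10 * tilt[:, 0]
        p2 = SurfaceMesh("p2", tilt, p2.faces)
        totals = []
        npairs = []
        for T in (0.03, 0.05, 0.08, 0.12):
            report, _, _ = interacting_regions(p1, p2, T=T)
            totals.append(report.total_area1)
            npairs.append(len(report.pairs))
        assert totals == sorted(totals)
        assert npairs == sorted(npairs)

    def test_refinement_grows_captured_area(self):
        # remeshing advice in practice: a finer grid captures more of the true
        # footprint because whole faces must fall inside the threshold
        captured = []
        for grid in (11, 21, 41):
            p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.0, grid=grid)
            tilt = p2.vertices.copy()
            tilt[:, 2] = 0.03 + 0.08 * tilt[:, 0]
            p2 = SurfaceMesh("p2", tilt, p2.faces)
            report, _, _ = interacting_regions(p1, p2, T=0.05)
            captured.append(report.pairs[0].area1 if report.pairs else 0.0)
        assert captured[0] < captured[-1]

    def test_any_vertex_mode_is_more_inclusive(self):
        p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.0, grid=21)
        tilt = p2.vertices.copy()
        tilt[:, 2] = 0.03 + 0.08 * tilt[:, 0]
        p2 = SurfaceMesh("p2", tilt, p2.faces)
        strict, _, _ = interacting_regions(p1, p2, T=0.05)
        loose, _, _ = interacting_regions(p1, p2, T=0.05, any_vertex=True)
        assert loose.total_area1 >= strict.total_area1

    def test_empty_mesh_rejected(self, unit_cube):
        empty = SurfaceMesh("e", np.empty((0, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            interacting_regions(unit_cube, empty, T=0.05)

    def test_report_csv_layout(self, tmp_path):
        p1, p2 = fixtures.make_plate_pair(side=1.0, gap=0.03, grid=11)
        report, _, _ = interacting_regions(p1, p2, T=0.05)
        path = tmp_path / "report.csv"
        write_interaction_report(report, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("region1,area1_um2")
        assert lines[-2].startswith("total_nonoverlap_area,plate1")
        assert lines[-1].startswith("total_nonoverlap_area,plate2")
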