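"""Heat maps, surface meshes, Delaunay triangulation and uniform remeshing."""

import numpy as np
import pytest

from locodist import (
    GeometryError,
    HeatMap,
    TimeInterval,
    build_heatmap,
    delaunay_triangulate,
    mesh_from_heatmap,
    refine_to_uniform,
    simulate_trajectory,
)
from locodist.synthetic import CRUISE

from conftest import smooth_random_heatmap


class TestBuildHeatmap:
    def test_stationary_subject_occupies_one_cell(self, arena):
        from locodist import Trajectory

        traj = Trajectory("s", np.arange(40) / 20.0, np.full(40, 55.0), np.full(40, 33.0), 20.0, arena)
        hm = build_heatmap(traj, grid=(10, 6))
        assert hm.rho.max() == 1.0
        assert (hm.rho > 0).sum() == 1

    def test_occupancy_conserved(self, cruise_traj, erratic_traj):
        for traj in (cruise_traj, erratic_traj):
            for grid in [(10, 6), (20, 12)]:
                hm = build_heatmap(traj, grid=grid)
                assert hm.rho.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(hm.rho >= 0)

    def test_uniform_wanderer_stays_near_uniform(self):
        traj = simulate_trajectory(CRUISE, 600.0, 20.0, seed=77, subject_id="w")
        hm = build_heatmap(traj, grid=(10, 6))
        assert hm.rho.max() < 3.0 / 60.0  # < 3x the uniform cell fraction

    def test_interval_slices_before_binning(self, cruise_traj):
        hm = build_heatmap(cruise_traj, TimeInterval(0.0, 30.0), grid=(10, 6))
        assert hm.interval.end == 30.0
        assert hm.rho.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fine_grid_warns(self, cruise_traj):
        with pytest.warns(UserWarning, match="tracking resolution"):
            build_heatmap(cruise_traj, grid=(600, 6))


class TestDelaunay:
    def test_triangle_from_three_points(self):
        res = delaunay_triangulate([[0, 0], [1, 0], [0, 1]])
        assert len(res.triangles) == 1

    def test_unit_square_gives_two_triangles(self):
        res = delaunay_triangulate([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert len(res.triangles) == 2
        shared = set(map(tuple, np.sort(res.triangles, axis=1)))
        assert len(shared) == 2

    def test_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            delaunay_triangulate([[0, 0], [1, 1], [2, 2], [3, 3]])

    def test_duplicates_removed_and_counted(self):
        res = delaunay_triangulate([[0, 0], [1, 0], [0, 1], [0, 0], [1, 0]])
        assert res.n_duplicates == 2
        assert len(res.points) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_empty_circumcircle_property(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (50, 2))
        res = delaunay_triangulate(pts)
        # brute force: no input point strictly inside any circumcircle
        for tri in res.triangles:
            a, b, c = res.points[tri]
            # circumcenter via perpendicular bisector solve
            d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
            ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
            uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
            center = np.array([ux, uy])
            r = np.linalg.norm(a - center)
            dist = np.linalg.norm(res.points - center, axis=1)
            assert np.all(dist >= r - 1e-9 * max(1.0, r))

    def test_matches_scipy_triangle_count(self):
        from scipy.spatial import Delaunay as SciPyDelaunay

        rng = np.random.default_rng(123)
        pts = rng.uniform(0, 10, (40, 2))
        ours = delaunay_triangulate(pts)
        ref = SciPyDelaunay(pts)
        assert len(ours.triangles) == len(ref.simplices)


class TestMeshFromHeatmap:
    def test_flat_heatmap_gives_planar_mesh(self, arena):
        hm = HeatMap(np.full((10, 6), 1.0 / 60.0), arena)
        mesh = mesh_from_heatmap(hm, z_scale=100.0)
        assert np.ptp(mesh.vertices[:, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_euler_characteristic_is_one(self, cruise_traj, erratic_traj):
        for traj in (cruise_traj, erratic_traj):
            hm = build_heatmap(traj, grid=(10, 6))
            mesh = mesh_from_heatmap(hm)
            v, e, f = len(mesh.vertices), len(mesh.edges), len(mesh.triangles)
            assert v - e + f == 1

    def test_surface_area_at_least_planar_area(self, erratic_traj, arena):
        hm = build_heatmap(erratic_traj, grid=(10, 6))
        mesh = mesh_from_heatmap(hm)
        assert mesh.triangle_areas(three_d=True).sum() > arena.area
        flat = mesh_from_heatmap(HeatMap(np.full((10, 6), 1 / 60), arena), z_scale=10.0)
        assert flat.triangle_areas(three_d=True).sum() == pytest.approx(arena.area, rel=1e-12)

    def test_vertex_rho_recovers_occupancy(self, cruise_traj):
        hm = build_heatmap(cruise_traj, grid=(10, 6))
        mesh = mesh_from_heatmap(hm, z_scale=50.0)
        # cell-center vertices come first, in row-major (x, y) order
        np.testing.assert_allclose(mesh.rho[: hm.rho.size], hm.rho.ravel(), atol=1e-12)

    def test_off_export_round_trip_header(self, tmp_path, cruise_traj):
        hm = build_heatmap(cruise_traj, grid=(10, 6))
        mesh = mesh_from_heatmap(hm)
        path = tmp_path / "mesh.off"
        mesh.write_off(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "OFF"
        nv, nf, _ = map(int, lines[1].split())
        assert (nv, nf) == (len(mesh.vertices), len(mesh.triangles))


class TestRefineToUniform:
    def test_already_uniform_mesh_unchanged(self, hex_wheel_mesh):
        # hex wheel edges are all length 1 -> ratio 1, returned as-is
        mesh = replace_domain(hex_wheel_mesh)
        assert refine_to_uniform(mesh, tol=0.2) is mesh

    def test_ratio_improves_substantially(self, arena):
        rng = np.random.default_rng(5)
        hm = smooth_random_heatmap(rng, arena)
        mesh = mesh_from_heatmap(hm)
        out = refine_to_uniform(mesh, tol=0.2, max_iters=40)
        assert out.uniformity_ratio() < 0.6 * mesh.uniformity_ratio()
        out.validate()

    def test_contract_ratio_or_flag(self, arena):
        rng = np.random.default_rng(6)
        for _ in range(3):
            hm = smooth_random_heatmap(rng, arena)
            mesh = mesh_from_heatmap(hm)
            out = refine_to_uniform(mesh, tol=0.2, max_iters=40)
            ok = out.uniformity_ratio() <= 1.2
            assert ok or out.warning_flags.get("refine_cap_reached", False)

    def test_achieves_tolerance_from_perturbed_lattice(self):
        # a perturbed equilateral lattice relaxes back into the tol = 0.2 band
        from locodist import Arena, TriMesh

        rng = np.random.default_rng(2)
        h = 10.0
        nx, ny = 10, 7
        w, hd = nx * h, (ny - 1) * h * np.sqrt(3) / 2
        pts = []
        for r in range(ny):
            y = r * h * np.sqrt(3) / 2
            if r % 2 == 0:
                xs = np.arange(nx + 1) * h
            else:
                xs = h / 2 + np.arange(nx) * h
            pts.extend((x, y) for x in xs)
        pts = np.array(pts)
        interior = (pts[:, 0] > 0) & (pts[:, 0] < w) & (pts[:, 1] > 0) & (pts[:, 1] < hd)
        pts[interior] += rng.uniform(-0.12 * h, 0.12 * h, (interior.sum(), 2))
        res = delaunay_triangulate(pts)
        mesh = TriMesh(
            np.column_stack([res.points, np.zeros(len(res.points))]),
            res.triangles,
            domain=Arena(w, hd),
        )
        assert mesh.uniformity_ratio() > 1.2  # the perturbation breaks the band
        out = refine_to_uniform(mesh, tol=0.2, max_iters=60)
        assert out.uniformity_ratio() <= 1.2
        assert "refine_cap_reached" not in out.warning_flags

    def test_vertex_count_grows_on_long_edges(self, arena):
        # one tall spike forces splitting
        rho = np.full((10, 6), 1.0)
        rho[5, 3] = 60.0
        hm = HeatMap(rho / rho.sum(), arena)
        mesh = mesh_from_heatmap(hm)
        out = refine_to_uniform(mesh, tol=0.2, max_iters=15)
        assert len(out.vertices) > len(mesh.vertices)


def replace_domain(mesh):
    """Attach a unit-circle bounding domain so refinement preconditions hold."""
    from dataclasses import replace

    from locodist import Arena

    if mesh.domain is not None:
        return mesh
    shifted = mesh.vertices.copy()
    shifted[:, 0] += 1.0
    shifted[:, 1] += 1.0
    return replace(
        mesh,
        vertices=shifted,
        triangles=mesh.triangles,
        domain=Arena(2.0, 2.0),
        warning_flags=dict(mesh.warning_flags),
    )
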