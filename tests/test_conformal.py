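"""Circle packing, Mobius maps, distortion energy and the CSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locodist import (
    ArgumentError,
    MobiusMap,
    Surface,
    build_heatmap,
    circle_pack,
    csd_distance,
    csd_from_alignment,
    default_z_scale,
    mesh_from_heatmap,
    mobius_apply,
    optimal_rotation_align,
    prepare_surface,
    refine_to_uniform,
    symmetric_distortion_energy,
)


disk_points = st.complex_numbers(max_magnitude=0.95, allow_nan=False, allow_infinity=False)


class TestMobius:
    def test_anchor_maps_to_origin(self):
        m = MobiusMap(0.3 + 0.4j, 1.2)
        assert abs(m(0.3 + 0.4j)) == pytest.approx(0.0, abs=1e-15)

    def test_unit_circle_preserved(self):
        m = MobiusMap(0.5j, 0.7)
        z = np.exp(1j * np.linspace(0, 2 * np.pi, 17))
        np.testing.assert_allclose(np.abs(m(z)), 1.0, atol=1e-12)

    def test_anchor_outside_disk_rejected(self):
        with pytest.raises(ArgumentError):
            MobiusMap(1.0 + 0j)

    @settings(max_examples=60, deadline=None)
    @given(disk_points, st.floats(0, 2 * np.pi), disk_points)
    def test_inverse_round_trip(self, a, theta, z):
        m = MobiusMap(a, theta)
        assert abs(m.inverse()(m(z)) - z) < 1e-10

    def test_identity_at_zero_anchor(self):
        m = MobiusMap(0j, 0.0)
        z = np.array([0.1 + 0.2j, -0.5j])
        np.testing.assert_allclose(mobius_apply(m, z), z, atol=1e-15)

    def test_composition_stays_in_disk(self):
        m1 = MobiusMap(0.4, 0.3)
        m2 = MobiusMap(-0.2 + 0.1j, 2.0)
        z = np.array([0.7, 0.2 - 0.6j, 0.0])
        assert np.all(np.abs(m2(m1(z))) < 1.0)


class TestCirclePack:
    def test_hexagonal_wheel_maximal_packing(self, hex_wheel_mesh):
        lay = circle_pack(hex_wheel_mesh, tol=1e-8)
        # the maximal packing of the wheel: all seven radii are exactly 1/3,
        # interior circle at the origin
        np.testing.assert_allclose(lay.radii, 1.0 / 3.0, atol=1e-6)
        assert abs(lay.centers[0]) < 1e-6
        assert lay.report["angle_error"] <= 1e-8

    def test_contract_on_heatmap_meshes(self, cruise_traj, erratic_traj):
        tol = 1e-8
        for traj in (cruise_traj, erratic_traj):
            hm = build_heatmap(traj, grid=(10, 6))
            mesh = refine_to_uniform(mesh_from_heatmap(hm), tol=0.2, max_iters=20)
            lay = circle_pack(mesh, tol=tol)
            assert lay.report["angle_error"] <= tol
            assert lay.report["tangency_residual"] <= 10 * tol
            # all circles inside the closed unit disk
            assert np.all(np.abs(lay.centers) + lay.radii <= 1.0 + 1e-7)

    def test_boundary_circles_tangent_to_unit_circle(self, hex_wheel_mesh):
        lay = circle_pack(hex_wheel_mesh)
        gap = np.abs(lay.centers[1:]) + lay.radii[1:] - 1.0
        assert np.max(np.abs(gap)) < 1e-7

    def test_flat_square_angle_distortion_shrinks_with_refinement(self, arena):
        # discrete conformal maps converge: the flattening's per-triangle
        # angle distortion decreases as the flat mesh is refined
        from locodist import HeatMap

        hm = HeatMap(np.full((6, 6), 1.0 / 36.0), arena)
        devs = []
        for iters in (0, 12):
            mesh = mesh_from_heatmap(hm, z_scale=1.0)
            if iters:
                mesh = refine_to_uniform(mesh, tol=0.05, max_iters=iters)
            lay = circle_pack(mesh)
            devs.append(_mean_angle_distortion(mesh, lay))
        assert devs[1] < devs[0]


def _mean_angle_distortion(mesh, lay):
    tri = mesh.triangles
    p3 = mesh.vertices
    zd = lay.centers

    def angles(a, b, c):
        u, v = b - a, c - a
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        dot = np.sum(u * v, axis=-1)
        return np.arccos(np.clip(dot / (nu * nv), -1, 1))

    devs = []
    for k in range(3):
        i, j, l = tri[:, k], tri[:, (k + 1) % 3], tri[:, (k + 2) % 3]
        a3 = angles(p3[i], p3[j], p3[l])
        zi = np.column_stack([zd[i].real, zd[i].imag])
        zj = np.column_stack([zd[j].real, zd[j].imag])
        zl = np.column_stack([zd[l].real, zd[l].imag])
        a2 = angles(zi, zj, zl)
        devs.append(np.abs(a3 - a2))
    return float(np.mean(devs))


class TestSymmetricDistortionEnergy:
    def test_identity_map_has_zero_energy(self, square_pair_meshes):
        a, _ = square_pair_meshes
        assert symmetric_distortion_energy(a, a, a.vertices, a.vertices) == 0.0

    def test_square_doubling_worked_example(self, square_pair_meshes):
        a, b = square_pair_meshes
        # forward: diagonal stretched 2x, A_ij = 1 -> sqrt(1/3);
        # reverse: shrunk to 1/2, A_ij = 4 -> sqrt(1/3); total = 2/sqrt(3)
        esd = symmetric_distortion_energy(a, b, 2.0 * a.vertices, 0.5 * b.vertices)
        assert esd == pytest.approx(2.0 / np.sqrt(3.0), abs=1e-12)

    def test_two_term_symmetry(self, square_pair_meshes):
        a, b = square_pair_meshes
        rng = np.random.default_rng(1)
        fwd = 2.0 * a.vertices + rng.normal(0, 0.05, a.vertices.shape)
        rev = 0.5 * b.vertices + rng.normal(0, 0.05, b.vertices.shape)
        assert symmetric_distortion_energy(a, b, fwd, rev) == pytest.approx(
            symmetric_distortion_energy(b, a, rev, fwd), abs=1e-12
        )

    def test_unmapped_vertices_rejected(self, square_pair_meshes):
        a, b = square_pair_meshes
        with pytest.raises(ArgumentError):
            symmetric_distortion_energy(a, b, a.vertices[:2], b.vertices)


@pytest.fixture(scope="module")
def two_surfaces(cruise_traj, erratic_traj):
    hm1 = build_heatmap(cruise_traj, grid=(10, 6))
    hm2 = build_heatmap(erratic_traj, grid=(10, 6))
    zs = default_z_scale(hm1, hm2)
    return prepare_surface(hm1, zs), prepare_surface(hm2, zs), hm1, hm2


class TestRotationAlignment:
    def test_self_alignment_recovers_identity(self, two_surfaces):
        s1, _, _, _ = two_surfaces
        al = optimal_rotation_align(s1, s1, n_angles=36)
        assert al.mobius.theta == pytest.approx(0.0)
        assert al.e_sd == pytest.approx(0.0, abs=1e-9)

    def test_argmin_over_angle_grid(self, two_surfaces):
        s1, s2, _, _ = two_surfaces
        al = optimal_rotation_align(s1, s2, n_angles=24)
        assert al.e_sd == pytest.approx(float(al.e_sd_by_angle.min()))
        k = int(np.argmin(al.e_sd_by_angle))
        assert al.mobius.theta == pytest.approx(float(al.angles[k]))

    def test_denser_angle_grid_never_worse(self, two_surfaces):
        s1, s2, _, _ = two_surfaces
        coarse = optimal_rotation_align(s1, s2, n_angles=18)
        fine = optimal_rotation_align(s1, s2, n_angles=36)  # nested grid
        assert fine.e_sd <= coarse.e_sd + 1e-12


class TestCsd:
    def test_self_distance_negligible(self, two_surfaces):
        _, _, hm1, _ = two_surfaces
        assert csd_distance(hm1, hm1, n_angles=36) <= 1e-6

    def test_symmetry(self, two_surfaces):
        _, _, hm1, hm2 = two_surfaces
        d12 = csd_distance(hm1, hm2, n_angles=36)
        d21 = csd_distance(hm2, hm1, n_angles=36)
        assert d12 == pytest.approx(d21, rel=1e-9)
        assert d12 > 0

    def test_mismatched_grids_rejected(self, cruise_traj):
        hma = build_heatmap(cruise_traj, grid=(10, 6))
        hmb = build_heatmap(cruise_traj, grid=(12, 8))
        with pytest.raises(ArgumentError):
            csd_distance(hma, hmb)

    def test_scale_consistency_with_frozen_alignment(self, two_surfaces):
        s1, s2, _, _ = two_surfaces
        al = optimal_rotation_align(s1, s2, n_angles=24)
        base = csd_from_alignment(al)
        scaled = csd_from_alignment(al, 3.0 * s1.mesh.rho, 3.0 * s2.mesh.rho)
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_esd_floor_decreases_with_refinement(self, cruise_traj):
        # discretization consistency: against a fixed fine surface, a refined
        # coarse surface aligns with lower distortion than the raw one
        hm = build_heatmap(cruise_traj, grid=(10, 6))
        base = mesh_from_heatmap(hm)
        mid = refine_to_uniform(base, tol=0.05, max_iters=4)
        fine = refine_to_uniform(base, tol=0.05, max_iters=40)
        s_base = Surface(base, circle_pack(base))
        s_mid = Surface(mid, circle_pack(mid))
        s_fine = Surface(fine, circle_pack(fine))
        e_raw = optimal_rotation_align(s_base, s_fine, n_angles=36).e_sd
        e_ref = optimal_rotation_align(s_mid, s_fine, n_angles=36).e_sd
        assert e_ref < e_raw
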