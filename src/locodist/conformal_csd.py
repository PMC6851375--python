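"""Conformal flattening and the Conformal Spatiotemporal Distance.

A heat-map surface (a triangulated topological disk) is flattened to the unit
disk by circle packing: each vertex gets a circle, adjacent circles are
tangent, and the radii are iterated until every interior vertex's angle sum is
2*pi.  Radii are solved in the hyperbolic metric of the disk with large fixed
boundary radii, which approximates the *maximal* packing — boundary circles
internally tangent to the unit circle — and the packing is then laid out in
the Poincare disk by breadth-first placement.

Conformal self-maps of the disk are Mobius transformations determined by the
point sent to the origin plus a rotation; aligning two flattened surfaces
therefore reduces to centering each packing on its surface centroid and brute
forcing the rotation that minimizes the symmetric distortion energy

    E_sd(f) ~ sqrt( sum (l(f(e))/l(e) - 1)^2 A_e/3 )
            + sqrt( sum (l(f^-1(e))/l(e) - 1)^2 A_e/3 ),

summed over interior edges, with A_e the area of the two triangles meeting at
e.  The CSD between two occupancy surfaces is the aligned, symmetrized,
area-normalized L2 distance between their occupancy functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, GeometryError, NumericError
from .heatmap_surface import (
    HeatMap,
    TriMesh,
    default_z_scale,
    mesh_from_heatmap,
    refine_to_uniform,
)
from .tracking_io import DistanceMatrix, TimeInterval, Trajectory

__all__ = [
    "DiskLayout",
    "MobiusMap",
    "BaryMap",
    "SurfaceAlignment",
    "Surface",
    "circle_pack",
    "mobius_apply",
    "symmetric_distortion_energy",
    "optimal_rotation_align",
    "prepare_surface",
    "csd_distance",
    "csd_from_alignment",
    "pairwise_csd",
]

#: fixed hyperbolic radius assigned to boundary circles; e^(-2*12) ~ 4e-11, so
#: boundary circles are horocycle-like and the layout approximates the maximal
#: packing to well below the contract tolerances.
_BOUNDARY_HYP_RADIUS = 12.0


# ---------------------------------------------------------------------------
# Mobius transformations of the unit disk
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MobiusMap:
    """Disk automorphism z -> e^{i theta} (z - a) / (1 - conj(a) z), |a| < 1."""

    a: complex = 0j
    theta: float = 0.0

    def __post_init__(self):
        if abs(self.a) >= 1:
            raise ArgumentError("Mobius anchor must lie inside the unit disk")

    def __call__(self, z):
        z = np.asarray(z, dtype=complex)
        return np.exp(1j * self.theta) * (z - self.a) / (1.0 - np.conj(self.a) * z)

    def inverse(self) -> "MobiusMap":
        return MobiusMap(-self.a * np.exp(1j * self.theta), -self.theta)


def mobius_apply(map: MobiusMap, points) -> np.ndarray:
    """Apply a disk Mobius transformation to complex points."""
    return map(points)


# ---------------------------------------------------------------------------
# Circle packing
# ---------------------------------------------------------------------------


@dataclass
class DiskLayout:
    """Circle-packing layout of a mesh in the unit disk.

    ``centers`` are complex circle centers, ``radii`` the Euclidean radii;
    indices correspond to mesh vertices.  ``report`` records the solver's
    convergence: max interior angle-sum deviation and max tangency residual.
    """

    centers: np.ndarray
    radii: np.ndarray
    boundary_vertex: np.ndarray
    report: dict = field(default_factory=dict)


def _hyp_angle(rv, ru, rw):
    """Angle at the circle of hyperbolic radius rv in a tangent triple.

    Uses the half-angle form 2*arcsin(sqrt(u(1-v)(1-w)/((1-uv)(1-uw)))) with
    u = e^{-2 rv} etc., which stays accurate for tiny angles at the large
    boundary radii (the plain arccos law-of-cosines form cancels
    catastrophically there).
    """
    u = np.exp(-2.0 * rv)
    v = np.exp(-2.0 * ru)
    w = np.exp(-2.0 * rw)
    s = u * (1.0 - v) * (1.0 - w) / ((1.0 - u * v) * (1.0 - u * w))
    return 2.0 * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def _interior_corners(mesh: TriMesh):
    """Flat corner lists (pivot, nbr1, nbr2) for corners at interior vertices."""
    t = mesh.triangles
    pivots = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    n1 = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    n2 = np.concatenate([t[:, 2], t[:, 0], t[:, 1]])
    keep = ~mesh.boundary_vertex[pivots]
    return pivots[keep], n1[keep], n2[keep]


def _solve_radii(mesh: TriMesh, tol: float, max_sweeps: int = 2000) -> np.ndarray:
    """Jacobi-Newton iteration on interior hyperbolic radii (angle sums 2*pi)."""
    nv = len(mesh.vertices)
    interior = ~mesh.boundary_vertex
    if not np.any(interior):
        raise GeometryError("circle packing needs at least one interior vertex")
    piv, n1, n2 = _interior_corners(mesh)
    r = np.where(interior, 0.5, _BOUNDARY_HYP_RADIUS).astype(float)

    def angle_sums(radii, bump=0.0):
        ang = _hyp_angle(radii[piv] + bump, radii[n1], radii[n2])
        out = np.zeros(nv)
        np.add.at(out, piv, ang)
        return out[interior]

    target = 2.0 * np.pi
    for sweep in range(max_sweeps):
        th = angle_sums(r)
        err = th - target
        resid = float(np.max(np.abs(err)))
        if resid < tol:
            return r
        h = 1e-7
        dth = (angle_sums(r, bump=h) - th) / h  # d(theta)/dr, negative
        dth = np.where(np.abs(dth) < 1e-14, -1e-14, dth)
        step = err / dth
        step = np.clip(step, -1.0, 1.0)
        rn = r[interior] - step
        r[interior] = np.clip(rn, 1e-6, 40.0)
    raise NumericError(f"circle packing did not converge: residual {resid:.3e}")


def _hyp_to_euclid(z_h: np.ndarray, r_hyp: np.ndarray):
    """Euclidean center/radius of hyperbolic circles (centers z_h in the disk)."""
    d = 2.0 * np.arctanh(np.clip(np.abs(z_h), 0.0, 1.0 - 1e-17))
    e1 = np.tanh((d - r_hyp) / 2.0)
    e2 = np.tanh((d + r_hyp) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(np.abs(z_h) > 0, z_h / np.where(np.abs(z_h) > 0, np.abs(z_h), 1.0), 1.0 + 0j)
    centers = 0.5 * (e1 + e2) * direction
    radii = 0.5 * (e2 - e1)
    return centers, radii


def _layout(mesh: TriMesh, r: np.ndarray) -> np.ndarray:
    """Breadth-first placement of hyperbolic circle centers in the disk."""
    nv = len(mesh.vertices)
    pos = np.full(nv, np.nan + 0j, dtype=complex)
    placed = np.zeros(nv, dtype=bool)

    # seed: the face with the most interior vertices, rotated so the pair of
    # smallest-radius vertices leads (placement errors scale with sinh of the
    # pivot-to-neighbour distance, so small circles make the best anchors)
    n_int = np.sum(~mesh.boundary_vertex[mesh.triangles], axis=1)
    seed = [int(v) for v in mesh.triangles[int(np.argmax(n_int))]]
    while not (r[seed[0]] <= r[seed[2]] and r[seed[1]] <= r[seed[2]]):
        seed = [seed[1], seed[2], seed[0]]
    i, j = seed[0], seed[1]
    pos[i] = 0j
    placed[i] = True
    pos[j] = np.tanh((r[i] + r[j]) / 2.0)
    placed[j] = True

    faces = [tuple(int(v) for v in f) for f in mesh.triangles]
    pending = set(range(len(faces)))
    progress = True
    while pending and progress:
        progress = False
        done = []
        for fi in sorted(pending):
            f = faces[fi]
            n_placed = sum(placed[v] for v in f)
            if n_placed == 3:
                done.append(fi)
                continue
            if n_placed != 2:
                continue
            ki = next(k for k in range(3) if not placed[f[k]])
            c = f[ki]
            p1, p2 = f[(ki + 1) % 3], f[(ki + 2) % 3]
            # pivot on the smaller circle for numerical stability; in the CCW
            # face cycle the unplaced vertex sits at +alpha from the pivot's
            # successor, -alpha from its predecessor
            a, b = (p1, p2) if r[p1] <= r[p2] else (p2, p1)
            sign = 1.0 if (f[(f.index(a) + 1) % 3] == b) else -1.0
            alpha = float(_hyp_angle(np.array(r[a]), np.array(r[b]), np.array(r[c])))
            za, zb = pos[a], pos[b]
            w_b = (zb - za) / (1.0 - np.conj(za) * zb)
            direction = w_b / abs(w_b)
            w_c = np.tanh((r[a] + r[c]) / 2.0) * direction * np.exp(1j * sign * alpha)
            pos[c] = (w_c + za) / (1.0 + np.conj(za) * w_c)
            placed[c] = True
            done.append(fi)
            progress = True
        pending.difference_update(done)
    if not np.all(placed):
        raise GeometryError("circle-packing layout could not reach every vertex")
    return pos


def _polish_packing(mesh: TriMesh, centers: np.ndarray, radii: np.ndarray):
    """Gauss-Newton polish of the Euclidean tangency system.

    The breadth-first layout accumulates tiny placement error; a few
    Gauss-Newton steps on the residuals |c_u - c_v| - (R_u + R_v) over all
    edges (unknowns: all centers and radii) drive tangency — and with it the
    radii-based angle sums — to machine precision without moving the packing
    more than the initial error.
    """
    import scipy.sparse as sp
    from scipy.sparse.linalg import lsqr

    e = mesh.edges
    ne, nv = len(e), len(radii)
    x = np.concatenate([centers.real, centers.imag, radii])
    rows = np.repeat(np.arange(ne), 6)
    for _ in range(8):
        dx = x[e[:, 0]] - x[e[:, 1]]
        dy = x[nv + e[:, 0]] - x[nv + e[:, 1]]
        d = np.hypot(dx, dy)
        f = d - (x[2 * nv + e[:, 0]] + x[2 * nv + e[:, 1]])
        if float(np.max(np.abs(f))) < 1e-14:
            break
        ux, uy = dx / d, dy / d
        cols = np.column_stack([
            e[:, 0], e[:, 1], nv + e[:, 0], nv + e[:, 1],
            2 * nv + e[:, 0], 2 * nv + e[:, 1],
        ]).ravel()
        vals = np.column_stack([ux, -ux, uy, -uy, -np.ones(ne), -np.ones(ne)]).ravel()
        J = sp.csr_matrix((vals, (rows, cols)), shape=(ne, 3 * nv))
        step = lsqr(J, -f, atol=1e-15, btol=1e-15)[0]
        x = x + step
    return x[:nv] + 1j * x[nv : 2 * nv], x[2 * nv :]


def _layout_report(mesh: TriMesh, centers: np.ndarray, radii: np.ndarray) -> dict:
    """Euclidean-side contract checks: interior angle sums and tangency."""
    piv, n1, n2 = _interior_corners(mesh)
    a = radii[piv] + radii[n1]
    b = radii[piv] + radii[n2]
    c = radii[n1] + radii[n2]
    cosang = np.clip((a * a + b * b - c * c) / (2.0 * a * b), -1.0, 1.0)
    sums = np.zeros(len(mesh.vertices))
    np.add.at(sums, piv, np.arccos(cosang))
    interior = ~mesh.boundary_vertex
    angle_err = float(np.max(np.abs(sums[interior] - 2.0 * np.pi)))
    e = mesh.edges
    gap = np.abs(centers[e[:, 0]] - centers[e[:, 1]]) - (radii[e[:, 0]] + radii[e[:, 1]])
    return {"angle_error": angle_err, "tangency_residual": float(np.max(np.abs(gap)))}


def circle_pack(mesh: TriMesh, tol: float = 1e-8) -> DiskLayout:
    """Maximal circle packing of a disk-topology mesh in the unit disk.

    Interior radii are iterated (Jacobi-Newton on exact hyperbolic angle
    sums) until every interior angle sum is within the solver tolerance of
    2*pi; boundary circles get a large fixed hyperbolic radius, making them
    internally tangent to the unit circle to well below ``tol``.
    """
    r = _solve_radii(mesh, tol=min(tol * 1e-2, 1e-10))
    z_h = _layout(mesh, r)
    centers, radii = _hyp_to_euclid(z_h, r)
    centers, radii = _polish_packing(mesh, centers, radii)
    report = _layout_report(mesh, centers, radii)
    if report["angle_error"] > tol:
        raise NumericError(f"packing angle error {report['angle_error']:.2e} exceeds {tol:.0e}")
    return DiskLayout(centers, radii, mesh.boundary_vertex.copy(), report)


# ---------------------------------------------------------------------------
# Surface alignment
# ---------------------------------------------------------------------------


@dataclass
class Surface:
    """A heat-map surface together with its disk flattening."""

    mesh: TriMesh
    layout: DiskLayout


@dataclass
class BaryMap:
    """Barycentric transfer table: for each source vertex, the target triangle
    (vertex index triple) and weights of its image point."""

    tri_vertices: np.ndarray  # (V, 3) int
    weights: np.ndarray       # (V, 3) float
    n_fallback: int = 0

    def interpolate(self, vertex_values: np.ndarray) -> np.ndarray:
        return np.sum(vertex_values[self.tri_vertices] * self.weights, axis=-1)

    def image_points(self, vertices: np.ndarray) -> np.ndarray:
        return np.einsum("vkd,vk->vd", vertices[self.tri_vertices], self.weights)


@dataclass
class SurfaceAlignment:
    """Result of the Mobius alignment of two flattened surfaces."""

    source: Surface
    target: Surface
    mobius: MobiusMap          # rotation applied between the centered layouts
    forward: BaryMap           # source vertices -> target surface
    reverse: BaryMap           # target vertices -> source surface
    e_sd: float
    angles: np.ndarray
    e_sd_by_angle: np.ndarray
    n_fallback: int = 0


def _weighted_centroid(surf: Surface) -> complex:
    w = surf.mesh.vertex_areas(three_d=False)
    return complex(np.sum(w * surf.layout.centers) / np.sum(w))


class _DiskLocator:
    """Point location + barycentric weights in a flattened triangulation."""

    def __init__(self, points: np.ndarray, triangles: np.ndarray):
        from matplotlib.tri import Triangulation

        self.xy = np.column_stack([points.real, points.imag])
        self.triangles = triangles
        self._tri = Triangulation(self.xy[:, 0], self.xy[:, 1], triangles)
        self._finder = self._tri.get_trifinder()

    def locate(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        """Triangle vertex triples and barycentric weights for complex points.

        Points outside the triangulated polygon (e.g. rotated slightly past
        the boundary) are shrunk radially toward the origin until they land
        inside; the number of such fallbacks is returned.
        """
        z = np.asarray(z, dtype=complex).ravel()
        x, y = z.real.copy(), z.imag.copy()
        t = np.asarray(self._finder(x, y))
        n_fallback = int(np.sum(t < 0))
        miss = t < 0
        shrink = 0.995
        for _ in range(400):
            if not np.any(miss):
                break
            x[miss] *= shrink
            y[miss] *= shrink
            t[miss] = self._finder(x[miss], y[miss])
            miss = t < 0
        if np.any(miss):
            raise GeometryError("point location failed even after shrinking to the origin")
        tv = self.triangles[t]
        a = self.xy[tv[:, 0]]
        b = self.xy[tv[:, 1]]
        c = self.xy[tv[:, 2]]
        p = np.column_stack([x, y])
        v0 = b - a
        v1 = c - a
        v2 = p - a
        den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        w1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
        w2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
        w0 = 1.0 - w1 - w2
        return tv, np.column_stack([w0, w1, w2]), n_fallback


def _distortion_term(mesh: TriMesh, image_points: np.ndarray) -> float:
    """One direction of the discrete symmetric distortion energy."""
    e = mesh.edges[mesh.interior_edge]
    ell = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    ell_img = np.linalg.norm(image_points[e[:, 0]] - image_points[e[:, 1]], axis=1)
    a_ij = mesh.edge_areas(three_d=True)[mesh.interior_edge]
    return float(np.sqrt(np.sum((ell_img / ell - 1.0) ** 2 * a_ij / 3.0)))


def symmetric_distortion_energy(
    meshA: TriMesh,
    meshB: TriMesh,
    forward_points: np.ndarray,
    reverse_points: np.ndarray,
) -> float:
    """Discrete symmetric distortion energy of a vertex map between surfaces.

    ``forward_points[v]`` is the 3-D image on B of vertex v of A;
    ``reverse_points`` the other direction.  Both sums run over interior
    edges only, with lengths measured in 3-space and A_ij the summed area of
    the two triangles adjacent to each edge.
    """
    if len(forward_points) != len(meshA.vertices) or len(reverse_points) != len(meshB.vertices):
        raise ArgumentError("vertex map must cover every vertex in both directions")
    return _distortion_term(meshA, np.asarray(forward_points, float)) + _distortion_term(
        meshB, np.asarray(reverse_points, float)
    )


def optimal_rotation_align(
    surfA: Surface,
    surfB: Surface,
    n_angles: int = 360,
) -> SurfaceAlignment:
    """Brute-force the disk rotation minimizing the symmetric distortion energy.

    Each layout is first centered by the Mobius map sending its area-weighted
    surface centroid to the origin; candidate maps f = f_B^{-1} o rot_theta
    o f_A are evaluated on an even grid of ``n_angles`` rotations (theta = 0
    included) by transferring vertices with planar point location plus
    barycentric interpolation, and the exact argmin over the grid is
    returned.
    """
    if n_angles < 1:
        raise ArgumentError("need at least one angle")
    mA = MobiusMap(_weighted_centroid(surfA))
    mB = MobiusMap(_weighted_centroid(surfB))
    zA = mA(surfA.layout.centers)
    zB = mB(surfB.layout.centers)
    locA = _DiskLocator(zA, surfA.mesh.triangles)
    locB = _DiskLocator(zB, surfB.mesh.triangles)
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles
    phase = np.exp(1j * angles)

    vA, vB = len(zA), len(zB)
    fwd_tv, fwd_w, nf1 = locB.locate((zA[None, :] * phase[:, None]).ravel())
    rev_tv, rev_w, nf2 = locA.locate((zB[None, :] * np.conj(phase)[:, None]).ravel())
    fwd_pts = np.einsum(
        "qkd,qk->qd", surfB.mesh.vertices[fwd_tv], fwd_w
    ).reshape(n_angles, vA, 3)
    rev_pts = np.einsum(
        "qkd,qk->qd", surfA.mesh.vertices[rev_tv], rev_w
    ).reshape(n_angles, vB, 3)

    def terms(mesh, pts):
        e = mesh.edges[mesh.interior_edge]
        ell = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
        a_ij = mesh.edge_areas(three_d=True)[mesh.interior_edge]
        d = np.linalg.norm(pts[:, e[:, 0], :] - pts[:, e[:, 1], :], axis=2)
        return np.sqrt(np.sum((d / ell - 1.0) ** 2 * a_ij / 3.0, axis=1))

    e_sd = terms(surfA.mesh, fwd_pts) + terms(surfB.mesh, rev_pts)
    best = int(np.argmin(e_sd))
    sl = slice(best * vA, (best + 1) * vA)
    forward = BaryMap(fwd_tv[sl], fwd_w[sl])
    sl = slice(best * vB, (best + 1) * vB)
    reverse = BaryMap(rev_tv[sl], rev_w[sl])
    return SurfaceAlignment(
        source=surfA,
        target=surfB,
        mobius=MobiusMap(0j, float(angles[best])),
        forward=forward,
        reverse=reverse,
        e_sd=float(e_sd[best]),
        angles=angles,
        e_sd_by_angle=e_sd,
        n_fallback=nf1 + nf2,
    )


# ---------------------------------------------------------------------------
# CSD
# ---------------------------------------------------------------------------


def prepare_surface(
    hm: HeatMap,
    z_scale: float | None = None,
    uniform_tol: float = 0.2,
    pack_tol: float = 1e-8,
    max_refine_iters: int = 30,
) -> Surface:
    """Heat map -> uniform triangulated surface -> circle-packing flattening."""
    mesh = mesh_from_heatmap(hm, z_scale)
    mesh = refine_to_uniform(mesh, tol=uniform_tol, max_iters=max_refine_iters)
    return Surface(mesh, circle_pack(mesh, tol=pack_tol))


def csd_from_alignment(
    alignment: SurfaceAlignment,
    rhoA: np.ndarray | None = None,
    rhoB: np.ndarray | None = None,
) -> float:
    """Aligned, normalized L2 distance between two occupancy functions.

    The integrals are discretized as vertex sums weighted by one third of the
    adjacent planar triangle areas; values of the other surface at image
    points come from the alignment's barycentric tables.  Passing ``rhoA`` /
    ``rhoB`` evaluates the same frozen alignment on different fields.
    """
    meshA, meshB = alignment.source.mesh, alignment.target.mesh
    if rhoA is None:
        rhoA = meshA.rho
    if rhoB is None:
        rhoB = meshB.rho
    wA = meshA.vertex_areas(three_d=False)
    wB = meshB.vertex_areas(three_d=False)
    d1 = rhoA - alignment.forward.interpolate(rhoB)
    d2 = rhoB - alignment.reverse.interpolate(rhoA)
    i1 = np.sqrt(np.sum(d1 * d1 * wA))
    i2 = np.sqrt(np.sum(d2 * d2 * wB))
    area = meshA.domain.area if meshA.domain is not None else float(np.sum(wA))
    return float((i1 + i2) / (2.0 * area))


def csd_distance(
    hm1: HeatMap,
    hm2: HeatMap,
    z_scale: float | None = None,
    uniform_tol: float = 0.2,
    pack_tol: float = 1e-8,
    n_angles: int = 360,
) -> float:
    """Conformal spatiotemporal distance between two occupancy heat maps.

    Both heat maps must share the same grid and arena.  A single z scale
    (default: joint peak at 25% of the arena diagonal) is used for both
    surfaces so the comparison is symmetric.
    """
    if hm1.grid != hm2.grid or hm1.arena != hm2.arena:
        raise ArgumentError("heat maps must share the same grid and arena")
    if z_scale is None:
        z_scale = default_z_scale(hm1, hm2)
    s1 = prepare_surface(hm1, z_scale, uniform_tol, pack_tol)
    s2 = prepare_surface(hm2, z_scale, uniform_tol, pack_tol)
    alignment = optimal_rotation_align(s1, s2, n_angles)
    return csd_from_alignment(alignment)


def pairwise_csd(
    cohort: list[Trajectory],
    interval: TimeInterval | None = None,
    grid: tuple[int, int] = (20, 12),
    z_scale: float | None = None,
    uniform_tol: float = 0.2,
    pack_tol: float = 1e-8,
    n_angles: int = 360,
) -> DistanceMatrix:
    """Symmetric matrix of CSD over all unordered pairs of a cohort.

    Each subject's surface is flattened once (with a z scale shared across
    the whole cohort), then aligned pairwise.
    """
    from .heatmap_surface import build_heatmap

    if len(cohort) < 2:
        raise ArgumentError("need at least 2 subjects")
    labels = [t.subject_id for t in cohort]
    if len(set(labels)) != len(labels):
        raise ArgumentError("duplicate subject labels in cohort")
    heatmaps = [build_heatmap(t, interval, grid) for t in cohort]
    if z_scale is None:
        z_scale = default_z_scale(*heatmaps)
    surfaces = [prepare_surface(hm, z_scale, uniform_tol, pack_tol) for hm in heatmaps]
    n = len(cohort)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            alignment = optimal_rotation_align(surfaces[i], surfaces[j], n_angles)
            vals[i, j] = vals[j, i] = csd_from_alignment(alignment)
    return DistanceMatrix(labels, vals, "CSD", interval)
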