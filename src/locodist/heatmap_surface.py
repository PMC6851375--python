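"""Occupancy heat maps and their triangulated surfaces.

The spatiotemporal distribution rho of a trajectory is the fraction of the
analysis window spent in each cell of an m x n grid over the arena.  Lifting
each grid node to height z = z_scale * rho turns the heat map into a surface
in R^3; the surface is triangulated (Bowyer-Watson Delaunay on the planar
projection — a function graph projects injectively), then remeshed toward
approximately uniform 3-D edge lengths, which the downstream circle-packing
flattening needs to approximate a conformal map well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError, GeometryError
from .tracking_io import Arena, TimeInterval, Trajectory, slice_interval

__all__ = [
    "HeatMap",
    "TriMesh",
    "DelaunayResult",
    "build_heatmap",
    "delaunay_triangulate",
    "mesh_from_heatmap",
    "refine_to_uniform",
    "default_z_scale",
]

#: tracking resolution of the source videos (mm); grids finer than this warn.
TRACKING_RESOLUTION_MM = 1.0 / 2.4

DEFAULT_GRID = (20, 12)  # ~1 cm cells for a 200 mm x 120 mm tank


@dataclass
class HeatMap:
    """Occupancy fractions on an m x n grid over a rectangular arena.

    ``rho[i, j]`` is the fraction of frames spent in cell i (along width) and
    j (along height); entries are nonnegative and sum to 1.
    """

    rho: np.ndarray
    arena: Arena
    subject_id: str = ""
    interval: TimeInterval | None = None

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 2 or min(self.rho.shape) < 2:
            raise ArgumentError("heat map grid must be at least 2 x 2")
        if np.any(self.rho < 0):
            raise DataError("occupancy fractions must be nonnegative")
        if abs(float(self.rho.sum()) - 1.0) > 1e-12:
            raise DataError("occupancy fractions must sum to 1")

    @property
    def grid(self) -> tuple[int, int]:
        return self.rho.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        m, n = self.rho.shape
        xc = (np.arange(m) + 0.5) * self.arena.width / m
        yc = (np.arange(n) + 0.5) * self.arena.height / n
        return xc, yc


def build_heatmap(
    traj: Trajectory,
    interval: TimeInterval | None = None,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> HeatMap:
    """Bin each frame's position into a grid cell; normalize by frame count.

    Cells are half-open with the right/top arena boundary assigned to the
    last cell (numpy.histogram2d's convention).
    """
    m, n = grid
    if m < 2 or n < 2:
        raise ArgumentError("grid must be at least 2 x 2")
    sub = slice_interval(traj, interval) if interval is not None else traj
    if traj.arena.width / m < TRACKING_RESOLUTION_MM or traj.arena.height / n < TRACKING_RESOLUTION_MM:
        warnings.warn(
            "heat-map cells are smaller than the tracking resolution "
            f"({TRACKING_RESOLUTION_MM:.2f} mm)",
            stacklevel=2,
        )
    counts, _, _ = np.histogram2d(
        sub.x, sub.y, bins=[m, n],
        range=[[0.0, traj.arena.width], [0.0, traj.arena.height]],
    )
    return HeatMap(counts / counts.sum(), traj.arena, sub.subject_id, interval)


# ---------------------------------------------------------------------------
# Bowyer-Watson Delaunay triangulation
# ---------------------------------------------------------------------------


@dataclass
class DelaunayResult:
    """Triangulation of a (deduplicated) planar point set."""

    points: np.ndarray       # (P, 2) unique points, input order preserved
    triangles: np.ndarray    # (T, 3) CCW vertex index triples
    n_duplicates: int = 0


def _incircle(pa, pb, pc, pd) -> np.ndarray:
    """> 0 where pd is inside the circumcircle of CCW triangle (pa, pb, pc).

    Vectorized over leading axes.
    """
    adx = pa[..., 0] - pd[..., 0]
    ady = pa[..., 1] - pd[..., 1]
    bdx = pb[..., 0] - pd[..., 0]
    bdy = pb[..., 1] - pd[..., 1]
    cdx = pc[..., 0] - pd[..., 0]
    cdy = pc[..., 1] - pd[..., 1]
    ad2 = adx * adx + ady * ady
    bd2 = bdx * bdx + bdy * bdy
    cd2 = cdx * cdx + cdy * cdy
    return (
        adx * (bdy * cd2 - cdy * bd2)
        - ady * (bdx * cd2 - cdx * bd2)
        + ad2 * (bdx * cdy - cdx * bdy)
    )


def delaunay_triangulate(points2d) -> DelaunayResult:
    """Incremental Bowyer-Watson Delaunay triangulation.

    Deterministic for a given input order: duplicates are removed keeping the
    first occurrence, points are inserted in input order into a fixed
    super-triangle, and near-cocircular ties are resolved by that order.
    Every output triangle has an empty circumcircle to within a relative
    tolerance of 1e-9.
    """
    raw = np.asarray(points2d, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ArgumentError("points2d must be an (n, 2) array")
    seen: dict[tuple[float, float], int] = {}
    keep = []
    for k, p in enumerate(map(tuple, raw)):
        if p not in seen:
            seen[p] = len(keep)
            keep.append(k)
    n_dup = len(raw) - len(keep)
    pts = raw[keep]
    n = len(pts)
    if n < 3:
        raise GeometryError("need at least 3 distinct points")

    # normalize into the unit box for predicate stability
    lo = pts.min(axis=0)
    span = float(max(np.ptp(pts, axis=0).max(), 1e-300))
    norm = (pts - lo) / span
    # collinearity: all points within 1e-12 of the line through the point
    # farthest from the first
    d0 = norm - norm[0]
    ref = d0[np.argmax(np.einsum("ij,ij->i", d0, d0))]
    if np.linalg.norm(ref) == 0:
        raise GeometryError("all points coincide")
    crosses = d0[:, 0] * ref[1] - d0[:, 1] * ref[0]
    if np.max(np.abs(crosses)) < 1e-12:
        raise GeometryError("all points are collinear")

    eps = 1e-9  # relative in-circle tolerance (unit box coordinates)
    big = 64.0
    sp = np.array([[-big, -big], [3 * big, -big], [0.5, 3 * big]])
    work = np.vstack([norm, sp])
    tri = [(n, n + 1, n + 2)]
    tri_arr = np.array(tri, dtype=np.int64)

    for p_idx in range(n):
        p = work[p_idx]
        a = work[tri_arr[:, 0]]
        b = work[tri_arr[:, 1]]
        c = work[tri_arr[:, 2]]
        bad = _incircle(a, b, c, p[None, :]) > eps
        if not np.any(bad):
            # on/outside every circumcircle within tolerance: nudge to the
            # nearest triangle by treating the least-negative as bad
            bad = np.zeros(len(tri_arr), dtype=bool)
            bad[np.argmax(_incircle(a, b, c, p[None, :]))] = True
        cavity = tri_arr[bad]
        # boundary edges of the cavity appear exactly once
        edges: dict[tuple[int, int], tuple[int, int]] = {}
        for t in cavity:
            for u, v in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                key = (min(u, v), max(u, v))
                if key in edges:
                    del edges[key]
                else:
                    edges[key] = (u, v)
        new_tris = [(u, v, p_idx) for (u, v) in edges.values()]
        tri_arr = np.vstack([tri_arr[~bad], np.array(new_tris, dtype=np.int64)])

    # drop triangles using super-triangle vertices
    tri_arr = tri_arr[np.all(tri_arr < n, axis=1)]
    # enforce CCW orientation
    a, b, c = work[tri_arr[:, 0]], work[tri_arr[:, 1]], work[tri_arr[:, 2]]
    signed = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    flip = signed < 0
    tri_arr[flip] = tri_arr[flip][:, [0, 2, 1]]
    return DelaunayResult(pts, tri_arr, n_dup)


# ---------------------------------------------------------------------------
# Triangulated surface
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Triangulated surface over a rectangular planar domain.

    ``vertices`` are (V, 3) points (x, y in mm, z = z_scale * rho);
    ``triangles`` are CCW (in the xy projection) vertex index triples.
    Derived edge/area quantities are computed on construction.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    z_scale: float = 1.0
    domain: Arena | None = None
    warning_flags: dict = field(default_factory=dict)

    # derived
    edges: np.ndarray = field(init=False)            # (E, 2) sorted index pairs
    interior_edge: np.ndarray = field(init=False)    # (E,) bool
    boundary_vertex: np.ndarray = field(init=False)  # (V,) bool

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ArgumentError("vertices must be (V, 3)")
        pairs = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        pairs = np.sort(pairs, axis=1)
        self.edges, counts = np.unique(pairs, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise GeometryError("an edge belongs to more than two triangles")
        self.interior_edge = counts == 2
        self.boundary_vertex = np.zeros(len(self.vertices), dtype=bool)
        be = self.edges[~self.interior_edge]
        self.boundary_vertex[be.ravel()] = True
        self.validate()

    # -- geometric quantities ------------------------------------------------

    def triangle_areas(self, three_d: bool = True) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        if three_d:
            return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        ab, ac = b[:, :2] - a[:, :2], c[:, :2] - a[:, :2]
        return 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])

    def edge_lengths(self, three_d: bool = True) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d if three_d else d[:, :2], axis=1)

    def edge_areas(self, three_d: bool = True) -> np.ndarray:
        """A_ij: per edge, the summed area of its adjacent triangles."""
        areas = self.triangle_areas(three_d)
        key = {tuple(e): k for k, e in enumerate(self.edges)}
        out = np.zeros(len(self.edges))
        for t_idx, t in enumerate(self.triangles):
            for u, v in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                out[key[(min(u, v), max(u, v))]] += areas[t_idx]
        return out

    def vertex_areas(self, three_d: bool = False) -> np.ndarray:
        """Lumped vertex weights: one third of adjacent triangle areas."""
        areas = self.triangle_areas(three_d) / 3.0
        out = np.zeros(len(self.vertices))
        np.add.at(out, self.triangles.ravel(), np.repeat(areas, 3))
        return out

    @property
    def rho(self) -> np.ndarray:
        """Occupancy value carried by each vertex (z / z_scale)."""
        return self.vertices[:, 2] / self.z_scale

    def uniformity_ratio(self) -> float:
        """max/min 3-D length over interior edges."""
        ell = self.edge_lengths(three_d=True)[self.interior_edge]
        return float(ell.max() / ell.min())

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        v = len(self.vertices)
        e = len(self.edges)
        f = len(self.triangles)
        if v - e + f != 1:
            raise GeometryError(f"not a topological disk: V-E+F = {v - e + f}")
        if np.any(self.triangle_areas(three_d=True) <= 1e-12):
            raise GeometryError("degenerate triangle (area <= 1e-12)")
        a = self.vertices[self.triangles[:, 0], :2]
        b = self.vertices[self.triangles[:, 1], :2]
        c = self.vertices[self.triangles[:, 2], :2]
        signed = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
        if np.any(signed <= 0):
            raise GeometryError("triangles must be consistently CCW in the xy projection")

    def write_off(self, path) -> None:
        """Export in OFF format for standard mesh viewers."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(self.vertices)} {len(self.triangles)} 0\n")
            for p in self.vertices:
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def default_z_scale(*heatmaps: HeatMap) -> float:
    """z scale making the tallest peak 25% of the domain diagonal.

    When several heat maps are passed (e.g. the two sides of a CSD), a single
    shared scale is computed from their joint maximum so the surfaces are
    comparable.
    """
    peak = max(float(hm.rho.max()) for hm in heatmaps)
    diag = heatmaps[0].arena.diagonal
    if peak <= 0:
        return 1.0
    return 0.25 * diag / peak


def _grid_vertices(hm: HeatMap) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center vertices plus a boundary ring; per-vertex rho values.

    Ring vertices carry the occupancy of their nearest cell, so a uniform
    heat map yields a perfectly flat surface.
    """
    m, n = hm.grid
    w, h = hm.arena.width, hm.arena.height
    xc, yc = hm.cell_centers()
    pts, vals = [], []
    for i in range(m):
        for j in range(n):
            pts.append((xc[i], yc[j]))
            vals.append(hm.rho[i, j])
    for i in range(m):  # bottom and top edges
        pts.append((xc[i], 0.0)); vals.append(hm.rho[i, 0])
        pts.append((xc[i], h)); vals.append(hm.rho[i, n - 1])
    for j in range(n):  # left and right edges
        pts.append((0.0, yc[j])); vals.append(hm.rho[0, j])
        pts.append((w, yc[j])); vals.append(hm.rho[m - 1, j])
    corners = [((0.0, 0.0), hm.rho[0, 0]), ((w, 0.0), hm.rho[m - 1, 0]),
               ((0.0, h), hm.rho[0, n - 1]), ((w, h), hm.rho[m - 1, n - 1])]
    for p, v in corners:
        pts.append(p); vals.append(v)
    return np.array(pts), np.array(vals)


def mesh_from_heatmap(hm: HeatMap, z_scale: float | None = None) -> TriMesh:
    """Lift a heat map to a triangulated surface in R^3.

    Vertices sit at cell centers plus a boundary ring along the arena walls;
    the planar point set is triangulated by Bowyer-Watson and each vertex is
    lifted to z = z_scale * rho.
    """
    if z_scale is None:
        z_scale = default_z_scale(hm)
    if z_scale <= 0:
        raise ArgumentError("z_scale must be positive")
    pts2d, vals = _grid_vertices(hm)
    res = delaunay_triangulate(pts2d)
    verts = np.column_stack([res.points, z_scale * vals])
    return TriMesh(verts, res.triangles, z_scale=z_scale, domain=hm.arena)


# ---------------------------------------------------------------------------
# Uniform remeshing
# ---------------------------------------------------------------------------


def _surface_interpolator(mesh: TriMesh):
    """Piecewise-linear z(x, y) over the mesh's planar triangulation."""
    from matplotlib.tri import LinearTriInterpolator, Triangulation

    tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    return tri, LinearTriInterpolator(tri, mesh.vertices[:, 2])


def _edges_counts(triangles: np.ndarray):
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0, return_counts=True)


def refine_to_uniform(
    mesh: TriMesh,
    tol: float = 0.2,
    max_iters: int = 60,
    relax_steps: int = 6,
) -> TriMesh:
    """Remesh toward uniform 3-D edge lengths.

    Each iteration merges very short interior edges, bisects very long ones
    (midpoint insertion; z always re-interpolated on the *input* surface,
    which remeshing treats as ground truth), slides vertices in the plane by
    spring relaxation of the interior edges toward their current geometric
    mid-length (boundary vertices slide along their wall, corners stay
    fixed — wall edges are excluded from the springs so corner fans can keep
    short wall spacing), and re-triangulates with Bowyer-Watson.

    Stops when the max/min interior 3-D edge-length ratio is at most
    ``1 + tol``.  On arbitrary spiky occupancy surfaces that band may be
    geometrically unreachable (triangulation defects force a residual spread);
    hitting ``max_iters`` then returns the best mesh seen with
    ``warning_flags['refine_cap_reached']`` set.
    """
    if tol <= 0:
        raise ArgumentError("tol must be positive")
    if mesh.domain is None:
        raise ArgumentError("refinement needs the mesh's planar domain")
    if mesh.uniformity_ratio() <= 1.0 + tol:
        return mesh
    w, h = mesh.domain.width, mesh.domain.height
    _, interp = _surface_interpolator(mesh)
    eps = 1e-9

    def z_at(p2d: np.ndarray) -> np.ndarray:
        q = np.clip(p2d, [0.0, 0.0], [w, h])
        z = interp(q[:, 0], q[:, 1])
        return np.asarray(z.filled(0.0)) if np.ma.isMaskedArray(z) else np.asarray(z)

    def on_wall(p: np.ndarray) -> bool:
        return p[0] < eps or p[0] > w - eps or p[1] < eps or p[1] > h - eps

    pts = mesh.vertices[:, :2].copy()
    best_pts, best_tris, best_ratio = None, None, np.inf
    target = 0.0  # fixed 3-D target length, set on the first pass
    max_vertices = max(8 * len(pts), 1500)

    for _ in range(max_iters):
        res = delaunay_triangulate(pts)
        pts, tris = res.points, res.triangles
        e, counts = _edges_counts(tris)
        interior = counts == 2
        p3 = np.column_stack([pts, z_at(pts)])
        ell = np.linalg.norm(p3[e[:, 0]] - p3[e[:, 1]], axis=1)
        li = ell[interior]
        ratio = float(li.max() / li.min())
        if ratio < best_ratio:
            best_pts, best_tris, best_ratio = pts.copy(), tris.copy(), ratio
        if ratio <= 1.0 + tol:
            verts = np.column_stack([pts, z_at(pts)])
            return TriMesh(verts, tris, z_scale=mesh.z_scale, domain=mesh.domain)
        if target == 0.0:
            target = float(np.median(li))
        # merge short interior edges (never touching wall vertices) and split
        # long ones; thresholds around the *fixed* target length, with
        # hysteresis so the two moves do not thrash
        drop: set[int] = set()
        for u, v in e[interior & (ell < 0.55 * target)]:
            u, v = int(u), int(v)
            if u in drop or v in drop:
                continue
            for q in (max(u, v), min(u, v)):
                if not on_wall(pts[q]):
                    drop.add(q)
                    break
        long = interior & (ell > 1.5 * target)
        if len(pts) >= max_vertices:
            long &= False
        mids = 0.5 * (pts[e[long, 0]] + pts[e[long, 1]])
        if drop or len(mids):
            keep = np.setdiff1d(np.arange(len(pts)), np.fromiter(drop, int, len(drop)))
            pts = np.vstack([pts[keep], mids])
            res = delaunay_triangulate(pts)
            pts, tris = res.points, res.triangles
            e, counts = _edges_counts(tris)
            interior = counts == 2
        # spring relaxation of interior edges toward the target length
        ei = e[interior]
        for _ in range(relax_steps):
            p3 = np.column_stack([pts, z_at(pts)])
            d2 = pts[ei[:, 1]] - pts[ei[:, 0]]
            l3 = np.maximum(np.linalg.norm(p3[ei[:, 1]] - p3[ei[:, 0]], axis=1), 1e-9)
            f = (target - l3) / l3
            force = np.zeros_like(pts)
            np.add.at(force, ei[:, 0], -0.15 * f[:, None] * d2)
            np.add.at(force, ei[:, 1], 0.15 * f[:, None] * d2)
            wall_x = (pts[:, 0] < eps) | (pts[:, 0] > w - eps)
            wall_y = (pts[:, 1] < eps) | (pts[:, 1] > h - eps)
            force[wall_x, 0] = 0.0
            force[wall_y, 1] = 0.0
            pts = np.clip(pts + force, [0.0, 0.0], [w, h])

    verts = np.column_stack([best_pts, z_at(best_pts)])
    out = TriMesh(verts, best_tris, z_scale=mesh.z_scale, domain=mesh.domain)
    out.warning_flags["refine_cap_reached"] = True
    return out
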