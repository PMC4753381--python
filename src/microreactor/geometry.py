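"""Chamber-minus-beads geometry and conforming triangulations.

The reaction chamber is the square (0, L)^2 with ``n_b`` circular beads of
diameter ``d`` removed; beads sit on a centered k x k grid (n_b = k^2).  The
boundary is tagged as import edge Gamma_i = {0} x (0,L), export edge
Gamma_e = {L} x (0,L), impermeable walls Gamma_0 (remaining chamber sides)
and bead surfaces Gamma_b (hole boundaries).

Bead-free chambers get an exact structured right-triangle mesh.  Chambers
with beads are meshed by force-equilibrated Delaunay smoothing in the style
of Persson & Strang's DistMesh: points spread over the domain by a signed
distance function, iteratively relaxed as a truss, retriangulated with
scipy's Delaunay, and finally snapped exactly onto the geometric features.
The mesher is deterministic (fixed internal seed and ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "BoundaryTag",
    "ChamberSpec",
    "TriangleMesh",
    "GeometryError",
    "place_beads",
    "build_chamber_mesh",
    "structured_square_mesh",
    "refine_uniform",
    "boundary_measures",
    "min_triangle_angle",
    "save_msh",
    "load_msh",
    "save_vtu",
]

_MESHER_SEED = 1729  # fixed: repeated builds must be identical


class GeometryError(ValueError):
    """Infeasible geometry or mesher failure."""


class BoundaryTag(IntEnum):
    INTERIOR = 0
    IMPORT = 1   # Gamma_i, x = 0
    EXPORT = 2   # Gamma_e, x = L
    WALL = 3     # Gamma_0
    BEAD = 4     # Gamma_b


@dataclass(frozen=True)
class ChamberSpec:
    """Square chamber of side ``L`` (m) with ``n_b`` beads of diameter ``d``.

    ``n_b`` must be 0 or a perfect square; beads are laid out on a centered
    uniform grid and must stay pairwise disjoint and clear of the walls.
    """

    L: float
    n_b: int
    d: float = 1e-5

    def __post_init__(self) -> None:
        if self.L <= 0 or self.d <= 0:
            raise GeometryError("L and d must be positive")
        k = round(np.sqrt(self.n_b)) if self.n_b else 0
        if self.n_b < 0 or k * k != self.n_b:
            raise GeometryError(f"n_b must be 0 or a perfect square, got {self.n_b}")

    @property
    def k(self) -> int:
        return int(round(np.sqrt(self.n_b))) if self.n_b else 0


def place_beads(spec: ChamberSpec) -> np.ndarray:
    """Bead centers on the centered k x k grid ((i+1/2) L/k, (j+1/2) L/k).

    Raises :class:`GeometryError` when beads would overlap each other or a
    wall (minimum clearance one bead radius).
    """
    if spec.n_b == 0:
        return np.zeros((0, 2))
    k = spec.k
    if np.sqrt(spec.n_b) * spec.d >= spec.L:
        raise GeometryError("bead grid does not fit the chamber")
    pitch = spec.L / k
    # pitch/2 is both the wall distance and half the center spacing;
    # require a clearance of one radius beyond the bead radius.
    if pitch < 2.0 * spec.d:
        raise GeometryError(
            f"beads too close: grid pitch {pitch:g} < 2 d = {2 * spec.d:g}")
    xs = (np.arange(k) + 0.5) * pitch
    cx, cy = np.meshgrid(xs, xs, indexing="ij")
    return np.column_stack([cx.ravel(), cy.ravel()])


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Conforming triangulation with tagged boundary facets.

    ``facets`` lists unique edges (vertex pairs); ``facet_cells[f]`` holds
    the one or two adjacent triangles (-1 for none); ``facet_normal[f]`` is
    the unit normal pointing out of ``facet_cells[f, 0]`` (outward normal on
    the boundary); ``cell_facets[K]`` gives the three facet ids of cell K and
    ``cell_facet_sign[K, i]`` is +1 when the facet normal is outward for K.
    """

    points: np.ndarray
    tris: np.ndarray
    facet_tags: np.ndarray = field(default=None)
    spec: ChamberSpec = None
    bead_centers: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tris = np.asarray(self.tris, dtype=np.int64)
        self._build_connectivity()
        if self.facet_tags is None:
            raise GeometryError("facet_tags required (use a mesh builder)")
        self.facet_tags = np.asarray(self.facet_tags, dtype=np.int64)
        if self.facet_tags.shape != (self.n_facets,):
            raise GeometryError("facet_tags has wrong length")
        bdry = self.facet_cells[:, 1] < 0
        if np.any((self.facet_tags == BoundaryTag.INTERIOR) & bdry):
            raise GeometryError("untagged boundary facet")
        if np.any((self.facet_tags != BoundaryTag.INTERIOR) & ~bdry):
            raise GeometryError("interior facet carries a boundary tag")

    def _build_connectivity(self) -> None:
        tris = self.tris
        pts = self.points
        # signed areas; enforce counterclockwise orientation
        v1 = pts[tris[:, 1]] - pts[tris[:, 0]]
        v2 = pts[tris[:, 2]] - pts[tris[:, 0]]
        area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        flip = area2 < 0
        tris[flip] = tris[flip][:, [0, 2, 1]]
        area2 = np.abs(area2)
        if np.any(area2 <= 0):
            raise GeometryError("degenerate (zero-area) triangle in mesh")
        self.tri_area = 0.5 * area2

        # unique edges; local edge i of a triangle is opposite vertex i
        edges = tris[:, [[1, 2], [2, 0], [0, 1]]].reshape(-1, 2)
        e_sorted = np.sort(edges, axis=1)
        facets, inv = np.unique(e_sorted, axis=0, return_inverse=True)
        self.facets = facets
        self.n_facets = len(facets)
        self.cell_facets = inv.reshape(-1, 3)

        facet_cells = np.full((self.n_facets, 2), -1, dtype=np.int64)
        for K in range(len(tris)):
            for i in range(3):
                f = self.cell_facets[K, i]
                if facet_cells[f, 0] < 0:
                    facet_cells[f, 0] = K
                elif facet_cells[f, 1] < 0:
                    facet_cells[f, 1] = K
                else:
                    raise GeometryError("non-conforming mesh: facet in >2 cells")
        self.facet_cells = facet_cells

        tang = pts[facets[:, 1]] - pts[facets[:, 0]]
        self.facet_length = np.hypot(tang[:, 0], tang[:, 1])
        normal = np.column_stack([tang[:, 1], -tang[:, 0]])
        normal /= self.facet_length[:, None]
        # orient normals out of facet_cells[:, 0]
        cent = pts[tris].mean(axis=1)
        mid = 0.5 * (pts[facets[:, 0]] + pts[facets[:, 1]])
        d0 = mid - cent[facet_cells[:, 0]]
        sgn = np.sign(np.einsum("ij,ij->i", d0, normal))
        sgn[sgn == 0] = 1.0
        self.facet_normal = normal * sgn[:, None]
        # sign of the facet normal relative to each cell's outward direction
        self.cell_facet_sign = np.where(
            self.facet_cells[self.cell_facets][:, :, 0]
            == np.arange(len(tris))[:, None], 1.0, -1.0)

    # -- convenience ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.tris)

    @property
    def cell_centroids(self) -> np.ndarray:
        return self.points[self.tris].mean(axis=1)

    @property
    def facet_midpoints(self) -> np.ndarray:
        return 0.5 * (self.points[self.facets[:, 0]] + self.points[self.facets[:, 1]])

    def facets_with_tag(self, tag: BoundaryTag) -> np.ndarray:
        return np.flatnonzero(self.facet_tags == tag)

    @property
    def area(self) -> float:
        return float(self.tri_area.sum())

    @property
    def max_edge_length(self) -> float:
        return float(self.facet_length.max())


def boundary_measures(mesh: TriangleMesh) -> dict:
    """Total lengths of the tagged boundary parts and the domain area."""
    out = {"area": mesh.area}
    for tag, name in ((BoundaryTag.IMPORT, "Gamma_i"), (BoundaryTag.EXPORT, "Gamma_e"),
                      (BoundaryTag.WALL, "Gamma_0"), (BoundaryTag.BEAD, "Gamma_b")):
        out[name] = float(mesh.facet_length[mesh.facets_with_tag(tag)].sum())
    return out


def min_triangle_angle(mesh: TriangleMesh) -> float:
    """Smallest interior angle of the triangulation, in degrees."""
    p = mesh.points[mesh.tris]
    angles = []
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return float(np.min(angles))


# ---------------------------------------------------------------------------
# geometric tagging
# ---------------------------------------------------------------------------

def _classify_facets(mesh_points, facets, facet_cells, L, centers, r):
    """Tag boundary facets by the feature both endpoints lie on."""
    n = len(facets)
    tags = np.zeros(n, dtype=np.int64)
    tol = 1e-9 * L
    bdry = np.flatnonzero(facet_cells[:, 1] < 0)
    for f in bdry:
        a, b = mesh_points[facets[f, 0]], mesh_points[facets[f, 1]]
        m = 0.5 * (a + b)
        if centers is not None and len(centers):
            dc = np.abs(np.hypot(*(m - centers).T) - r)
            if dc.min() < 0.25 * r:
                tags[f] = BoundaryTag.BEAD
                continue
        if abs(a[0]) < tol and abs(b[0]) < tol:
            tags[f] = BoundaryTag.IMPORT
        elif abs(a[0] - L) < tol and abs(b[0] - L) < tol:
            tags[f] = BoundaryTag.EXPORT
        elif (abs(a[1]) < tol and abs(b[1]) < tol) or \
             (abs(a[1] - L) < tol and abs(b[1] - L) < tol):
            tags[f] = BoundaryTag.WALL
        else:
            # fall back to the nearest feature of the midpoint
            cand = [(abs(m[0]), BoundaryTag.IMPORT), (abs(m[0] - L), BoundaryTag.EXPORT),
                    (abs(m[1]), BoundaryTag.WALL), (abs(m[1] - L), BoundaryTag.WALL)]
            tags[f] = min(cand)[1]
    return tags


def _tagged_mesh(points, tris, spec, centers):
    pts = np.asarray(points, dtype=float)
    tris = np.asarray(tris, dtype=np.int64)
    # build connectivity once to find boundary facets, then tag
    probe = object.__new__(TriangleMesh)
    probe.points = pts
    probe.tris = tris.copy()
    probe._build_connectivity()
    r = spec.d / 2.0 if spec is not None else 0.0
    tags = _classify_facets(probe.points, probe.facets, probe.facet_cells,
                            spec.L, centers, r)
    return TriangleMesh(probe.points, probe.tris, facet_tags=tags, spec=spec,
                        bead_centers=centers)


# ---------------------------------------------------------------------------
# structured meshes (bead-free chambers)
# ---------------------------------------------------------------------------

def structured_square_mesh(L: float, n: int, spec: ChamberSpec = None) -> TriangleMesh:
    """Uniform right-triangle mesh of (0, L)^2 with n x n cells per side."""
    if n < 1:
        raise GeometryError("n must be >= 1")
    xs = np.linspace(0.0, L, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):
        return i * (n + 1) + j

    tris = []
    for i in range(n):
        for j in range(n):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    if spec is None:
        spec = ChamberSpec(L=L, n_b=0)
    return _tagged_mesh(pts, np.array(tris), spec, np.zeros((0, 2)))


# ---------------------------------------------------------------------------
# DistMesh-style mesher for chambers with beads
# ---------------------------------------------------------------------------

def _fd_chamber(p, L, centers, r):
    """Signed distance to the chamber-minus-beads domain (negative inside)."""
    x, y = p[:, 0], p[:, 1]
    d_rect = -np.minimum(np.minimum(x, L - x), np.minimum(y, L - y))
    if len(centers) == 0:
        return d_rect
    d_circ = np.min(np.hypot(x[:, None] - centers[None, :, 0],
                             y[:, None] - centers[None, :, 1]), axis=1) - r
    return np.maximum(d_rect, -d_circ)


def _fh_chamber(p, L, centers, r, h_bead, h_far, grad=0.3):
    if len(centers) == 0:
        return np.full(len(p), h_far)
    d_circ = np.min(np.hypot(p[:, 0, None] - centers[None, :, 0],
                             p[:, 1, None] - centers[None, :, 1]), axis=1) - r
    return np.minimum(h_far, h_bead + grad * np.maximum(d_circ, 0.0))


def _project_to_features(p, L, centers, r, max_move):
    """Snap points exactly onto the nearest geometric feature (side/circle)."""
    q = p.copy()
    for i, pt in enumerate(p):
        cands = [(abs(pt[0]), (0.0, pt[1])), (abs(pt[0] - L), (L, pt[1])),
                 (abs(pt[1]), (pt[0], 0.0)), (abs(pt[1] - L), (pt[0], L))]
        if len(centers):
            dc = np.hypot(*(pt - centers).T)
            j = int(np.argmin(np.abs(dc - r)))
            c = centers[j]
            if dc[j] > 0:
                proj = c + (pt - c) * (r / dc[j])
                cands.append((abs(dc[j] - r), tuple(proj)))
        dist, proj = min(cands, key=lambda t: t[0])
        if dist <= max_move[i]:
            q[i] = proj
            # snap to a corner when close to two sides
            for cx in (0.0, L):
                for cy in (0.0, L):
                    if np.hypot(q[i, 0] - cx, q[i, 1] - cy) <= max_move[i]:
                        q[i] = (cx, cy)
    return q


def _distmesh(L, centers, r, h_bead, h_far, grading=0.3, max_iter=150):
    rng = np.random.default_rng(_MESHER_SEED)
    fd = lambda p: _fd_chamber(p, L, centers, r)
    fh = lambda p: _fh_chamber(p, L, centers, r, h_bead, h_far, grading)
    h0 = h_bead
    geps = 1e-3 * h0
    deps = np.sqrt(np.finfo(float).eps) * h0
    dptol, ttol, Fscale, deltat = 1e-3, 0.1, 1.2, 0.2

    # initial points: equilateral lattice, density-thinned by 1/fh^2
    nx = int(np.ceil(L / h0)) + 1
    ny = int(np.ceil(L / (h0 * np.sqrt(3) / 2))) + 1
    xs = np.linspace(0, L, nx)
    ys = np.linspace(0, L, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    X[:, 1::2] += h0 / 2.0
    p = np.column_stack([X.ravel(), Y.ravel()])
    p = p[fd(p) < geps]
    r0 = 1.0 / fh(p) ** 2
    p = p[rng.random(len(p)) < r0 / r0.max()]

    pfix = np.array([[0.0, 0.0], [L, 0.0], [0.0, L], [L, L]])
    keep = np.ones(len(p), dtype=bool)
    for q in pfix:
        keep &= np.hypot(p[:, 0] - q[0], p[:, 1] - q[1]) > h0
    p = np.vstack([pfix, p[keep]])
    nfix = len(pfix)

    pold = np.full_like(p, np.inf)
    tris = None
    for _ in range(max_iter):
        if np.max(np.hypot(*(p - pold).T)) > ttol * h0:
            pold = p.copy()
            dt_tri = Delaunay(p)
            cent = p[dt_tri.simplices].mean(axis=1)
            tris = dt_tri.simplices[fd(cent) < -geps]
            bars = np.unique(np.sort(
                tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1), axis=0)
        vec = p[bars[:, 0]] - p[bars[:, 1]]
        Lb = np.hypot(vec[:, 0], vec[:, 1])
        hbars = fh(0.5 * (p[bars[:, 0]] + p[bars[:, 1]]))
        L0 = hbars * Fscale * np.sqrt((Lb**2).sum() / (hbars**2).sum())
        F = np.maximum(L0 - Lb, 0.0)
        Fvec = (F / Lb)[:, None] * vec
        Ftot = np.zeros_like(p)
        np.add.at(Ftot, bars[:, 0], Fvec)
        np.add.at(Ftot, bars[:, 1], -Fvec)
        Ftot[:nfix] = 0.0
        p = p + deltat * Ftot

        d = fd(p)
        out = d > 0
        if np.any(out):
            dgx = (fd(p[out] + [deps, 0]) - d[out]) / deps
            dgy = (fd(p[out] + [0, deps]) - d[out]) / deps
            g2 = dgx**2 + dgy**2
            g2[g2 == 0] = 1.0
            p[out] -= (d[out] / g2)[:, None] * np.column_stack([dgx, dgy])
        interior = d < -geps
        if np.any(interior):
            move = deltat * np.hypot(*(Ftot[interior]).T)
            if move.max() / h0 < dptol:
                break

    # final: snap boundary vertices exactly onto the features and rebuild
    dt_tri = Delaunay(p)
    cent = p[dt_tri.simplices].mean(axis=1)
    tris = dt_tri.simplices[fd(cent) < -geps]
    bedges = _boundary_edges(tris)
    bverts = np.unique(bedges)
    max_move = 0.5 * fh(p)
    p[bverts] = _project_to_features(p[bverts], L, centers, r, max_move[bverts])

    # quality repair: slivers left by the truss relaxation are removed by
    # snapping near-boundary apexes onto the boundary and Laplacian-moving
    # interior vertices of low-angle triangles
    for _ in range(8):
        dt_tri = Delaunay(p)
        cent = p[dt_tri.simplices].mean(axis=1)
        tris = dt_tri.simplices[fd(cent) < -geps]
        bad = _low_angle_tris(p, tris, 22.0)
        if not len(bad):
            break
        bverts = set(np.unique(_boundary_edges(tris)))
        nbrs = {}
        bars = np.unique(np.sort(
            tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1), axis=0)
        for a, b in bars:
            nbrs.setdefault(a, []).append(b)
            nbrs.setdefault(b, []).append(a)
        for v in np.unique(tris[bad]):
            if v < nfix:
                continue
            hv = fh(p[v:v + 1])[0]
            if fd(p[v:v + 1])[0] > -0.35 * hv:
                p[v] = _project_to_features(p[v:v + 1], L, centers, r,
                                            np.array([0.5 * hv]))[0]
            elif v not in bverts:
                p[v] = p[nbrs[v]].mean(axis=0)

    dt_tri = Delaunay(p)
    cent = p[dt_tri.simplices].mean(axis=1)
    tris = dt_tri.simplices[fd(cent) < -geps]
    # drop unused points
    used = np.unique(tris)
    remap = -np.ones(len(p), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return p[used], remap[tris]


def _low_angle_tris(p, tris, threshold_deg):
    q = p[tris]
    mn = np.full(len(tris), 180.0)
    for i in range(3):
        a = q[:, (i + 1) % 3] - q[:, i]
        b = q[:, (i + 2) % 3] - q[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1) + 1e-300)
        mn = np.minimum(mn, np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return np.flatnonzero(mn < threshold_deg)


def _boundary_edges(tris):
    edges = np.sort(tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq[counts == 1]


def build_chamber_mesh(spec: ChamberSpec, resolution: float,
                       bead_resolution: float = None,
                       grading: float = 0.3) -> TriangleMesh:
    """Conforming triangulation of the chamber with circular bead holes.

    ``resolution`` is the target edge length away from the beads;
    ``bead_resolution`` the edge length on the bead surfaces (default d/8,
    giving ~25 segments per bead so the polygonal perimeter is within 0.5%
    of pi*d).  At least 16 segments per bead circumference are required.
    ``grading`` controls how fast the edge length grows away from the beads
    (dimensionless growth rate of the size field).
    """
    centers = place_beads(spec)
    if spec.n_b == 0:
        n = max(2, int(round(spec.L / resolution)))
        return structured_square_mesh(spec.L, n, spec=spec)
    r = spec.d / 2.0
    h_bead = bead_resolution if bead_resolution is not None else spec.d / 8.0
    h_bead = min(h_bead, resolution)
    if np.pi * spec.d / h_bead < 16.0 - 1e-9:
        raise GeometryError(
            "bead_resolution too coarse: need >= 16 segments per bead circumference")
    pts, tris = _distmesh(spec.L, centers, r, h_bead, resolution, grading)
    mesh = _tagged_mesh(pts, tris, spec, centers)
    _validate_chamber_mesh(mesh, spec, h_bead)
    return mesh


def _validate_chamber_mesh(mesh, spec, h_bead):
    # inscribed polygons fall short of the circle by ~(h/r)^2/24 relative;
    # allow that deficit on top of a 0.5% base tolerance
    r = spec.d / 2.0
    tol = 5e-3 + (h_bead / r) ** 2 / 12.0
    exact = spec.L**2 - spec.n_b * np.pi * r**2
    if abs(mesh.area - exact) > tol * exact:
        raise GeometryError(
            f"mesh area {mesh.area:g} deviates from |Omega| = {exact:g}")
    m = boundary_measures(mesh)
    if spec.n_b and abs(m["Gamma_b"] - spec.n_b * np.pi * spec.d) > \
            tol * spec.n_b * np.pi * spec.d:
        raise GeometryError("bead perimeter deviates from n_b*pi*d")


def refine_uniform(mesh: TriangleMesh) -> TriangleMesh:
    """Red refinement: split every triangle into four via edge midpoints.

    Midpoints of bead-surface facets are projected back onto the circles so
    the polygonal bead approximation converges under refinement.
    """
    pts = mesh.points
    mids = mesh.facet_midpoints.copy()
    if mesh.bead_centers is not None and len(mesh.bead_centers):
        r = mesh.spec.d / 2.0
        for f in mesh.facets_with_tag(BoundaryTag.BEAD):
            c = mesh.bead_centers[np.argmin(
                np.hypot(*(mids[f] - mesh.bead_centers).T))]
            v = mids[f] - c
            mids[f] = c + v * (r / np.hypot(*v))
    new_pts = np.vstack([pts, mids])
    off = len(pts)
    tris = []
    for K in range(mesh.n_cells):
        v = mesh.tris[K]
        # local facet i is opposite vertex i
        m = off + mesh.cell_facets[K]
        tris.extend([[v[0], m[2], m[1]], [v[1], m[0], m[2]],
                     [v[2], m[1], m[0]], [m[0], m[1], m[2]]])
    return _tagged_mesh(new_pts, np.array(tris), mesh.spec,
                        mesh.bead_centers if mesh.bead_centers is not None
                        else np.zeros((0, 2)))


# ---------------------------------------------------------------------------
# interchange formats (Gmsh MSH 2.2 ASCII, VTU ASCII)
# ---------------------------------------------------------------------------

def save_msh(mesh: TriangleMesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII format.

    Boundary facets become 2-node line elements whose physical tag is the
    :class:`BoundaryTag` value; triangles carry physical tag 0.
    """
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(len(mesh.points))]
    for i, (x, y) in enumerate(mesh.points, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} 0")
    lines.append("$EndNodes")
    bfacets = np.flatnonzero(mesh.facet_tags != BoundaryTag.INTERIOR)
    lines += ["$Elements", str(len(bfacets) + mesh.n_cells)]
    eid = 1
    for f in bfacets:
        a, b = mesh.facets[f] + 1
        t = int(mesh.facet_tags[f])
        lines.append(f"{eid} 1 2 {t} {t} {a} {b}")
        eid += 1
    for K in range(mesh.n_cells):
        a, b, c = mesh.tris[K] + 1
        lines.append(f"{eid} 2 2 0 0 {a} {b} {c}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_msh(path) -> TriangleMesh:
    """Read a mesh written by :func:`save_msh` (tags preserved)."""
    with open(path) as fh:
        txt = fh.read().split("\n")
    it = iter(txt)
    pts, tris, tagged = [], [], {}
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                pts.append([float(parts[1]), float(parts[2])])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                nodes = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 1:
                    tagged[tuple(sorted(nodes))] = int(parts[3])
                elif etype == 2:
                    tris.append(nodes)
    pts = np.asarray(pts)
    tris = np.asarray(tris, dtype=np.int64)
    probe = object.__new__(TriangleMesh)
    probe.points = pts
    probe.tris = tris
    probe._build_connectivity()
    tags = np.zeros(probe.n_facets, dtype=np.int64)
    for f in range(probe.n_facets):
        key = tuple(sorted(probe.facets[f]))
        if key in tagged:
            tags[f] = tagged[key]
    return TriangleMesh(pts, probe.tris, facet_tags=tags)


def save_vtu(mesh: TriangleMesh, path, cell_data: dict = None) -> None:
    """Write the mesh (plus optional per-cell scalar fields) as ASCII VTU."""
    n_p, n_c = len(mesh.points), mesh.n_cells
    out = ['<?xml version="1.0"?>',
           '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
           "<UnstructuredGrid>",
           f'<Piece NumberOfPoints="{n_p}" NumberOfCells="{n_c}">',
           '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">']
    out += [f"{x:.17g} {y:.17g} 0" for x, y in mesh.points]
    out += ["</DataArray></Points>", "<Cells>",
            '<DataArray type="Int64" Name="connectivity" format="ascii">']
    out += [" ".join(map(str, t)) for t in mesh.tris]
    out += ["</DataArray>", '<DataArray type="Int64" Name="offsets" format="ascii">',
            " ".join(str(3 * (i + 1)) for i in range(n_c)),
            "</DataArray>", '<DataArray type="UInt8" Name="types" format="ascii">',
            " ".join(["5"] * n_c), "</DataArray>", "</Cells>"]
    if cell_data:
        out.append("<CellData>")
        for name, vals in cell_data.items():
            out.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            out.append(" ".join(f"{v:.17g}" for v in np.asarray(vals).ravel()))
            out.append("</DataArray>")
        out.append("</CellData>")
    out += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
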