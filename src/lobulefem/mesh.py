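"""Idealized liver-lobule geometries.

The liver lobule is modelled as a regular hexagon: blood enters at the six
portal-triad corners (and optionally at venules on the edge midpoints) and
drains at a small central-vein region, which is cut out of the mesh so its
rim can carry an outflow boundary condition.  A group of seven lobules is the
hexagonal tessellation of one centre lobule and its six neighbours.

Meshes are structured triangulations (each hexagon is split into six sectors,
each subdivided into n^2 congruent triangles), which keeps refinement
deterministic and the boundary exactly on the hexagon.  Derived fields:

* ``zeta`` -- porto-central coordinate in [0, 1], 0 on the inflow boundary,
  1 on the central vein, computed from graph (approximate geodesic)
  distances; zones 1-3 (periportal / mid / pericentral) are thirds of zeta.
* ``aniso_dir`` -- per-cell unit vector toward the owning lobule's central
  vein, the preferred sinusoid direction used by the transverse-isotropic
  permeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

TAG_INFLOW_PORTAL = "inflow_portal"
TAG_INFLOW_VENULE = "inflow_venule"
TAG_OUTFLOW_CENTRAL = "outflow_central"
TAG_WALL = "wall"
ALL_TAGS = (TAG_INFLOW_PORTAL, TAG_INFLOW_VENULE, TAG_OUTFLOW_CENTRAL, TAG_WALL)
INFLOW_TAGS = (TAG_INFLOW_PORTAL, TAG_INFLOW_VENULE)


class MeshError(ValueError):
    """Invalid mesh-generation input or inconsistent mesh."""


@dataclass
class LobuleMesh:
    """2D triangulated lobule domain with tagged boundaries.

    vertices : (N, 2) coordinates [m]
    cells : (M, 3) triangle connectivity (counter-clockwise)
    boundary_edges : (E, 2) vertex pairs on the boundary
    boundary_tags : (E,) tag per boundary edge, one of ALL_TAGS
    lobule_id : (M,) owning lobule per cell
    lobule_centers : (L, 2) hexagon centres
    zeta : (N,) porto-central coordinate (filled by porto_central_field)
    aniso_dir : (M, 2) unit vector toward the central vein per cell
    """

    vertices: np.ndarray
    cells: np.ndarray
    boundary_edges: np.ndarray
    boundary_tags: np.ndarray
    lobule_id: np.ndarray
    lobule_centers: np.ndarray
    circumradius: float
    zeta: np.ndarray | None = None
    aniso_dir: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- derived geometry -------------------------------------------------
    def cell_areas(self) -> np.ndarray:
        p = self.vertices[self.cells]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def cell_centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def total_area(self) -> float:
        return float(self.cell_areas().sum())

    def boundary_nodes(self, tags) -> np.ndarray:
        """Sorted unique vertex indices on boundary edges with any of *tags*."""
        if isinstance(tags, str):
            tags = (tags,)
        mask = np.isin(self.boundary_tags, list(tags))
        return np.unique(self.boundary_edges[mask])

    def n_lobules(self) -> int:
        return len(self.lobule_centers)

    def validate(self) -> None:
        areas = self.cell_areas()
        if np.any(areas <= 0):
            raise MeshError("mesh contains inverted or degenerate triangles")
        if len(self.boundary_edges) != len(self.boundary_tags):
            raise MeshError("boundary tag array does not match boundary edges")
        unknown = set(np.unique(self.boundary_tags)) - set(ALL_TAGS)
        if unknown:
            raise MeshError(f"unknown boundary tags: {sorted(unknown)}")
        # tags must partition the boundary: extracted edges are tagged 1:1 by
        # construction, so it suffices that every boundary edge appears once
        seen = {tuple(sorted(e)) for e in self.boundary_edges}
        if len(seen) != len(self.boundary_edges):
            raise MeshError("duplicate boundary edges (tags would overlap)")


# ---------------------------------------------------------------------------
# structured hexagon triangulation
# ---------------------------------------------------------------------------

def _hex_corners(center: np.ndarray, r: float) -> np.ndarray:
    # corners at 30 + k*60 deg, so that group neighbours sit at k*60 deg
    # (and one lobule of the 7-group lies directly to the left)
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    return center[None, :] + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)


class _NodePool:
    """Deduplicates vertices shared between sectors/lobules by quantization."""

    def __init__(self, tol: float):
        self.tol = tol
        self._index: dict[tuple[int, int], int] = {}
        self.coords: list[np.ndarray] = []

    def add(self, p: np.ndarray) -> int:
        key = (int(round(p[0] / self.tol)), int(round(p[1] / self.tol)))
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.coords)
            self._index[key] = idx
            self.coords.append(p)
        return idx


def _subdivide_sector(pool: _NodePool, O, A, B, n: int, cells: list):
    """Subdivide triangle (O, A, B) into n^2 congruent triangles."""
    idx = {}
    for i in range(n + 1):
        for j in range(n + 1 - i):
            p = O + (i / n) * (A - O) + (j / n) * (B - O)
            idx[(i, j)] = pool.add(p)
    for i in range(n):
        for j in range(n - i):
            cells.append((idx[(i, j)], idx[(i + 1, j)], idx[(i, j + 1)]))
            if i + j < n - 1:
                cells.append((idx[(i + 1, j)], idx[(i + 1, j + 1)], idx[(i, j + 1)]))


def _mesh_hexagons(centers: np.ndarray, r: float, n: int):
    pool = _NodePool(tol=1e-9 * r)
    cells: list = []
    lobule_of_cell: list = []
    for li, c in enumerate(centers):
        corners = _hex_corners(c, r)
        start = len(cells)
        for k in range(6):
            _subdivide_sector(pool, c, corners[k], corners[(k + 1) % 6], n, cells)
        lobule_of_cell.extend([li] * (len(cells) - start))
    verts = np.asarray(pool.coords, dtype=float)
    tris = np.asarray(cells, dtype=np.int64)
    return verts, tris, np.asarray(lobule_of_cell, dtype=np.int64)


def _boundary_edges_of(cells: np.ndarray) -> np.ndarray:
    edges = np.concatenate([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return uniq[counts == 1]


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance of points p (Q,2) to segment a-b, and projection parameter t."""
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1), t


def _owning_lobule_of_edges(mesh_cells, lobule_id, edges):
    """lobule_id of the (unique) cell adjacent to each boundary edge."""
    edge_map = {}
    for ci, tri in enumerate(mesh_cells):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edge_map[tuple(sorted((tri[a], tri[b])))] = ci
    return np.array([lobule_id[edge_map[tuple(sorted(e))]] for e in edges])


def _tag_edges(verts, edges, owners, centers, r, corner_frac, venule_frac, venules):
    """Classify boundary edges as portal / venule / central-vein / wall."""
    tags = np.empty(len(edges), dtype=object)
    mids = 0.5 * (verts[edges[:, 0]] + verts[edges[:, 1]])
    geo_tol = 1e-6 * r
    for li in np.unique(owners):
        sel = np.where(owners == li)[0]
        c = centers[li]
        corners = _hex_corners(c, r)
        m = mids[sel]
        # distance to the owning hexagon's outline
        dist_out = np.full(len(sel), np.inf)
        t_edge = np.zeros(len(sel))
        k_edge = np.zeros(len(sel), dtype=int)
        for k in range(6):
            d, t = _point_segment_distance(m, corners[k], corners[(k + 1) % 6])
            closer = d < dist_out
            dist_out[closer] = d[closer]
            t_edge[closer] = t[closer]
            k_edge[closer] = k
        on_outline = dist_out < geo_tol
        tags[sel[~on_outline]] = TAG_OUTFLOW_CENTRAL  # central-vein rim
        out = sel[on_outline]
        d_corner = np.min(
            np.linalg.norm(mids[out][:, None, :] - corners[None, :, :], axis=2), axis=1
        )
        is_portal = d_corner < corner_frac * r
        tags[out[is_portal]] = TAG_INFLOW_PORTAL
        rest = out[~is_portal]
        if venules:
            is_ven = np.abs(t_edge[on_outline][~is_portal] - 0.5) < 0.5 * venule_frac
            tags[rest[is_ven]] = TAG_INFLOW_VENULE
            tags[rest[~is_ven]] = TAG_WALL
        else:
            tags[rest] = TAG_WALL
    return tags


def _cut_central_veins(verts, cells, lobule_id, centers, r, central_frac, n):
    """Remove cells inside each lobule's central-vein disc."""
    cen = verts[cells].mean(axis=1)
    keep = np.ones(len(cells), dtype=bool)
    h = r / n
    r_cv = max(central_frac * r, 1.05 * h)  # resolve at least one cell ring
    for li, c in enumerate(centers):
        d = np.linalg.norm(cen - c[None, :], axis=1)
        touches_center = np.any(
            np.linalg.norm(verts[cells] - c[None, None, :], axis=2) < 1e-9 * r, axis=1
        )
        keep &= ~((lobule_id == li) & ((d < r_cv) | touches_center))
    return cells[keep], lobule_id[keep], r_cv


def _compress(verts, cells, lobule_id):
    used = np.unique(cells)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[cells], lobule_id


def _build(centers, circumradius, target_edge_length, venules,
           corner_frac, venule_frac, central_frac) -> LobuleMesh:
    r = float(circumradius)
    if r <= 0:
        raise MeshError("circumradius must be positive")
    if not (0 < target_edge_length < r / 4):
        raise MeshError("target_edge_length must lie in (0, circumradius/4)")
    n = max(4, int(round(r / target_edge_length)))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    verts, cells, lobule_id = _mesh_hexagons(centers, r, n)
    cells, lobule_id, r_cv = _cut_central_veins(
        verts, cells, lobule_id, centers, r, central_frac, n
    )
    verts, cells, lobule_id = _compress(verts, cells, lobule_id)
    edges = _boundary_edges_of(cells)
    owners = _owning_lobule_of_edges(cells, lobule_id, edges)
    tags = _tag_edges(verts, edges, owners, centers, r, corner_frac, venule_frac, venules)
    if not np.any(np.isin(tags, list(INFLOW_TAGS))):
        raise MeshError(
            "mesh too coarse to resolve the portal-corner / venule inflow "
            "bands; decrease target_edge_length (need roughly <= "
            f"{2 * corner_frac:.2f} * circumradius)")
    mesh = LobuleMesh(
        vertices=verts, cells=cells, boundary_edges=edges, boundary_tags=tags,
        lobule_id=lobule_id, lobule_centers=centers, circumradius=r,
        meta={"n_subdiv": n, "r_central_vein": r_cv, "venules": bool(venules),
              "corner_frac": corner_frac, "venule_frac": venule_frac},
    )
    mesh.validate()
    mesh.aniso_dir = anisotropy_direction(mesh)
    mesh.zeta = porto_central_field(mesh)
    return mesh


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

DEFAULT_CIRCUMRADIUS = 5.0e-4  # m; physiological order of magnitude


def build_single_lobule(circumradius: float = DEFAULT_CIRCUMRADIUS,
                        target_edge_length: float | None = None,
                        venules: bool = True,
                        corner_frac: float = 0.08,
                        venule_frac: float = 0.15,
                        central_frac: float = 0.08) -> LobuleMesh:
    """Mesh one idealized hexagonal lobule.

    Inflow: six portal corner regions, plus venule segments at the edge
    midpoints if *venules*.  Outflow: the central-vein rim.
    """
    if target_edge_length is None:
        target_edge_length = circumradius / 16
    return _build(np.zeros((1, 2)), circumradius, target_edge_length, venules,
                  corner_frac, venule_frac, central_frac)


def build_lobule_group(rings: int = 1,
                       circumradius: float = DEFAULT_CIRCUMRADIUS,
                       target_edge_length: float | None = None,
                       venules: bool = True,
                       corner_frac: float = 0.08,
                       venule_frac: float = 0.15,
                       central_frac: float = 0.08) -> LobuleMesh:
    """Mesh the conforming group of seven tessellated lobules (rings=1)."""
    if rings != 1:
        raise MeshError("only rings=1 (a group of 7 lobules) is supported")
    if target_edge_length is None:
        target_edge_length = circumradius / 12
    r = circumradius
    ang = np.deg2rad(60.0 * np.arange(6))
    neigh = np.sqrt(3.0) * r * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    centers = np.vstack([np.zeros((1, 2)), neigh])
    return _build(centers, circumradius, target_edge_length, venules,
                  corner_frac, venule_frac, central_frac)


def rectangle_mesh(lx: float, ly: float, nx: int, ny: int) -> LobuleMesh:
    """Structured strip mesh; left edge inflow, right edge outflow.

    Used for analytic Darcy / transport verification problems.
    """
    x = np.linspace(0.0, lx, nx + 1)
    y = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel()], axis=1)
    idx = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
    cells = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            cells.append((a, b, c))
            cells.append((a, c, d))
    cells = np.asarray(cells, dtype=np.int64)
    edges = _boundary_edges_of(cells)
    mids = 0.5 * (verts[edges[:, 0]] + verts[edges[:, 1]])
    tol = 1e-9 * max(lx, ly)
    tags = np.full(len(edges), TAG_WALL, dtype=object)
    tags[mids[:, 0] < tol] = TAG_INFLOW_PORTAL
    tags[mids[:, 0] > lx - tol] = TAG_OUTFLOW_CENTRAL
    mesh = LobuleMesh(
        vertices=verts, cells=cells, boundary_edges=edges, boundary_tags=tags,
        lobule_id=np.zeros(len(cells), dtype=np.int64),
        lobule_centers=np.array([[lx, ly]]) * 0.5, circumradius=max(lx, ly),
        meta={"kind": "rectangle"},
    )
    mesh.validate()
    mesh.aniso_dir = np.tile([1.0, 0.0], (len(cells), 1))
    mesh.zeta = np.clip(verts[:, 0] / lx, 0.0, 1.0)
    return mesh


def annulus_mesh(r_inner: float, r_outer: float, n_r: int, n_theta: int) -> LobuleMesh:
    """Structured annulus; outer rim inflow, inner rim outflow."""
    if not 0 < r_inner < r_outer:
        raise MeshError("need 0 < r_inner < r_outer")
    rr = np.linspace(r_inner, r_outer, n_r + 1)
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts = np.stack(
        [np.outer(rr, np.cos(th)).ravel(), np.outer(rr, np.sin(th)).ravel()], axis=1
    )
    idx = np.arange((n_r + 1) * n_theta).reshape(n_r + 1, n_theta)
    cells = []
    for i in range(n_r):
        for j in range(n_theta):
            jp = (j + 1) % n_theta
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, jp], idx[i, jp]
            cells.append((a, b, c))
            cells.append((a, c, d))
    cells = np.asarray(cells, dtype=np.int64)
    edges = _boundary_edges_of(cells)
    mids = 0.5 * (verts[edges[:, 0]] + verts[edges[:, 1]])
    rad = np.linalg.norm(mids, axis=1)
    tags = np.where(rad > 0.5 * (r_inner + r_outer),
                    TAG_INFLOW_PORTAL, TAG_OUTFLOW_CENTRAL).astype(object)
    mesh = LobuleMesh(
        vertices=verts, cells=cells, boundary_edges=edges, boundary_tags=tags,
        lobule_id=np.zeros(len(cells), dtype=np.int64),
        lobule_centers=np.zeros((1, 2)), circumradius=r_outer,
        meta={"kind": "annulus"},
    )
    mesh.validate()
    mesh.aniso_dir = anisotropy_direction(mesh)
    rv = np.linalg.norm(verts, axis=1)
    mesh.zeta = np.clip((r_outer - rv) / (r_outer - r_inner), 0.0, 1.0)
    return mesh


# ---------------------------------------------------------------------------
# derived fields
# ---------------------------------------------------------------------------

def _node_graph(mesh: LobuleMesh, cell_mask=None):
    cells = mesh.cells if cell_mask is None else mesh.cells[cell_mask]
    e = np.concatenate([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = len(mesh.vertices)
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([e[:, 0], e[:, 1]]),
                     np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
    return g.tocsr()


def _min_dist(graph, sources):
    d = dijkstra(graph, directed=False, indices=sources)
    return d.min(axis=0) if d.ndim == 2 else d


def outline_inflow_nodes(mesh: LobuleMesh, lobule: int,
                         corner_frac: float | None = None,
                         venule_frac: float | None = None,
                         venules: bool | None = None) -> np.ndarray:
    """Portal-corner and venule nodes on one lobule's hexagon outline.

    Determined geometrically, so interior portal fields of a lobule group
    (which carry no boundary tag) are included; defaults come from the
    fractions the mesh was built with.
    """
    r = mesh.circumradius
    corner_frac = mesh.meta.get("corner_frac", 0.08) if corner_frac is None \
        else corner_frac
    venule_frac = mesh.meta.get("venule_frac", 0.15) if venule_frac is None \
        else venule_frac
    venules = mesh.meta.get("venules", True) if venules is None else venules
    corners = _hex_corners(mesh.lobule_centers[lobule], r)

    def classify(points):
        """corner/venule-band membership of outline points."""
        d_out = np.full(len(points), np.inf)
        t_par = np.zeros(len(points))
        for k in range(6):
            d, t = _point_segment_distance(points, corners[k], corners[(k + 1) % 6])
            closer = d < d_out
            d_out[closer] = d[closer]
            t_par[closer] = t[closer]
        on_outline = d_out < 1e-6 * r
        d_corner = np.min(np.linalg.norm(points[:, None, :] - corners[None, :, :],
                                         axis=2), axis=1)
        sel = on_outline & (d_corner < corner_frac * r)
        if venules:
            sel |= on_outline & (np.abs(t_par - 0.5) < 0.5 * venule_frac)
        return sel, on_outline

    # preferred route: classify boundary edges by their midpoints, exactly
    # mirroring the boundary tagger, so sealed-group lobules see the same
    # effective inflow bands as a standalone lobule at equal resolution
    owners = _owning_lobule_of_edges(mesh.cells, mesh.lobule_id,
                                     mesh.boundary_edges)
    own_edges = mesh.boundary_edges[owners == lobule]
    if len(own_edges):
        mids = 0.5 * (mesh.vertices[own_edges[:, 0]]
                      + mesh.vertices[own_edges[:, 1]])
        sel, on_outline = classify(mids)
        if np.any(on_outline):
            return np.unique(own_edges[sel])
    # fallback (interior lobule of a connected group): node-based test
    nodes = np.unique(mesh.cells[mesh.lobule_id == lobule])
    sel, _ = classify(mesh.vertices[nodes])
    return nodes[sel]


def porto_central_field(mesh: LobuleMesh) -> np.ndarray:
    """Normalized geodesic porto-central coordinate zeta in [0, 1].

    zeta = d_in / (d_in + d_out) with graph distances from the inflow
    boundary (d_in) and to the central vein (d_out), computed per lobule.
    Lobules without tagged inflow (interior lobules of a sealed group) fall
    back to their full hexagon periphery as the inflow surrogate.
    """
    if len(mesh.boundary_edges) == 0:
        raise MeshError("mesh has no tagged boundary")
    owners = _owning_lobule_of_edges(mesh.cells, mesh.lobule_id, mesh.boundary_edges)
    zeta = np.full(len(mesh.vertices), np.nan)
    for li in range(mesh.n_lobules()):
        cmask = mesh.lobule_id == li
        graph = _node_graph(mesh, cmask)
        lob_nodes = np.unique(mesh.cells[cmask])
        own = owners == li
        inflow_mask = own & np.isin(mesh.boundary_tags, list(INFLOW_TAGS))
        central_mask = own & (mesh.boundary_tags == TAG_OUTFLOW_CENTRAL)
        central = np.unique(mesh.boundary_edges[central_mask])
        if central.size == 0:
            # obstructed lobule whose vein rim was re-tagged: use geometry
            c = mesh.lobule_centers[li]
            r_cv = mesh.meta.get("r_central_vein", 0.1 * mesh.circumradius)
            d = np.linalg.norm(mesh.vertices[lob_nodes] - c[None, :], axis=1)
            central = lob_nodes[d < 1.3 * r_cv]
        if mesh.meta.get("n_subdiv"):
            # built lobule geometry: portal corners + venules on the full
            # hexagon outline (interior portal fields included)
            sources = outline_inflow_nodes(mesh, li)
        else:
            sources = np.unique(mesh.boundary_edges[inflow_mask])
        if sources.size == 0:
            sources = np.unique(mesh.boundary_edges[inflow_mask])
        d_in = _min_dist(graph, sources)[lob_nodes]
        d_cv = _min_dist(graph, central)[lob_nodes]
        with np.errstate(invalid="ignore"):
            z = d_in / (d_in + d_cv)
        z[np.isin(lob_nodes, sources)] = 0.0
        z[np.isin(lob_nodes, central)] = 1.0
        zeta[lob_nodes] = z
    if np.any(np.isnan(zeta)):
        raise MeshError("porto-central field undefined on some nodes")
    return np.clip(zeta, 0.0, 1.0)


def zone_of(zeta: np.ndarray) -> np.ndarray:
    """Zone 1 (periportal, zeta<1/3), 2 (mid), 3 (pericentral, zeta>=2/3)."""
    return np.where(zeta < 1.0 / 3.0, 1, np.where(zeta < 2.0 / 3.0, 2, 3))


def anisotropy_direction(mesh: LobuleMesh) -> np.ndarray:
    """Per-cell unit vector from the cell centroid toward the owning
    lobule's central vein."""
    cen = mesh.cell_centroids()
    d = mesh.lobule_centers[mesh.lobule_id] - cen
    norm = np.linalg.norm(d, axis=1)
    degenerate = norm < 1e-14 * max(mesh.circumradius, 1.0)
    if np.any(degenerate):
        d[degenerate] = (1.0, 0.0)
        norm[degenerate] = 1.0
        mesh.meta["aniso_fallback_cells"] = int(degenerate.sum())
    return d / norm[:, None]


# ---------------------------------------------------------------------------
# sealing lobule interfaces (presets i / ii)
# ---------------------------------------------------------------------------

def seal_lobule_interfaces(mesh: LobuleMesh) -> LobuleMesh:
    """Duplicate nodes on lobule-lobule interfaces so each lobule becomes an
    independent hydraulic compartment; interface edges are tagged as walls.

    Models the scenario family in which neighbouring lobules exchange no
    blood (presets i and ii); the connected mesh is kept for preset iii.
    """
    n_old = len(mesh.vertices)
    node_lobules: list[set] = [set() for _ in range(n_old)]
    for tri, li in zip(mesh.cells, mesh.lobule_id):
        for v in tri:
            node_lobules[v].add(int(li))
    new_coords = [mesh.vertices]
    remap: dict[tuple[int, int], int] = {}
    next_id = n_old
    for v, lobs in enumerate(node_lobules):
        lobs = sorted(lobs)
        if not lobs:
            continue
        remap[(v, lobs[0])] = v  # first lobule keeps the original node
        for li in lobs[1:]:
            remap[(v, li)] = next_id
            new_coords.append(mesh.vertices[v][None, :])
            next_id += 1
    verts = np.concatenate(new_coords, axis=0)
    cells = mesh.cells.copy()
    for ci, (tri, li) in enumerate(zip(mesh.cells, mesh.lobule_id)):
        for k, v in enumerate(tri):
            cells[ci, k] = remap[(v, int(li))]
    edges = _boundary_edges_of(cells)
    # carry over tags for surviving old edges; new (interface) edges -> wall
    old_tags = {tuple(sorted(e)): t
                for e, t in zip(mesh.boundary_edges, mesh.boundary_tags)}
    orig = {new: old for (old, _li), new in remap.items()}
    tags = np.empty(len(edges), dtype=object)
    for i, e in enumerate(edges):
        key = tuple(sorted((orig.get(e[0], e[0]), orig.get(e[1], e[1]))))
        tags[i] = old_tags.get(key, TAG_WALL)
    sealed = LobuleMesh(
        vertices=verts, cells=cells, boundary_edges=edges, boundary_tags=tags,
        lobule_id=mesh.lobule_id.copy(), lobule_centers=mesh.lobule_centers.copy(),
        circumradius=mesh.circumradius,
        meta=dict(mesh.meta, sealed=True),
    )
    sealed.validate()
    sealed.aniso_dir = anisotropy_direction(sealed)
    sealed.zeta = porto_central_field(sealed)
    return sealed
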