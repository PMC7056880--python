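"""Unstructured triangular meshing of the LV fluid domain.

The mesher resamples the geometry boundary at a target spacing (locally
refined near the lesion and septal crest), seeds interior points on a
hexagonal lattice plus graded wall layers, and triangulates with Delaunay,
keeping triangles whose centroid falls inside the fluid polygon.  Boundary
conformity (every resampled boundary segment present as a triangle edge) is
verified and is part of the meshing contract.  Everything is deterministic.

Mesh coordinates are in metres; geometry input is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, cKDTree
import shapely
from shapely.geometry import Polygon

from .geometry import LVGeometry, OPEN_TAGS

__all__ = ["MeshError", "TriMesh", "generate_mesh", "structured_rect_mesh",
           "remesh_interior"]

MM = 1e-3


class MeshError(RuntimeError):
    """Mesh generation or conformity failure."""


@dataclass
class TriMesh:
    """Triangle mesh with tagged boundary edges.

    ``bedges`` lists boundary edges as node-index pairs ordered along the
    boundary walk; ``btags`` carries the geometry tag of each edge and
    ``bnode_s`` the loop arc-length coordinate (mm, at build time) of every
    boundary node, used to map contour motion onto the mesh.
    """

    points: np.ndarray                 # (n, 2) metres
    tris: np.ndarray                   # (m, 3) int
    bedges: np.ndarray                 # (nb, 2) int
    btags: np.ndarray                  # (nb,) object
    bnode_s: dict = field(default_factory=dict)   # node -> s (mm)
    cell_size: float = 0.0             # metres
    first_layer: float = 0.0           # metres

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.tris)

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.bedges)

    def edges_with_tag(self, *tags) -> np.ndarray:
        mask = np.isin(self.btags, tags)
        return self.bedges[mask]

    def nodes_with_tag(self, *tags) -> np.ndarray:
        return np.unique(self.edges_with_tag(*tags))

    def tri_areas(self, points: Optional[np.ndarray] = None) -> np.ndarray:
        p = self.points if points is None else points
        a, b, c = p[self.tris[:, 0]], p[self.tris[:, 1]], p[self.tris[:, 2]]
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))

    def total_area(self) -> float:
        return float(self.tri_areas().sum())

    def boundary_polygon_area(self, points: Optional[np.ndarray] = None
                              ) -> float:
        """Area enclosed by the ordered boundary walk (signed, CCW > 0)."""
        p = self.points if points is None else points
        i, j = self.bedges[:, 0], self.bedges[:, 1]
        return 0.5 * float(np.sum(p[i, 0] * p[j, 1] - p[j, 0] * p[i, 1]))

    def boundary_loop_points(self) -> np.ndarray:
        """Boundary node coordinates ordered along the walk."""
        return self.points[self.bedges[:, 0]]

    def min_quality(self, points: Optional[np.ndarray] = None) -> float:
        """Minimum radius-ratio quality (2 r_in / r_circ), in (0, 1]."""
        p = self.points if points is None else points
        a = p[self.tris[:, 0]]
        b = p[self.tris[:, 1]]
        c = p[self.tris[:, 2]]
        la = np.linalg.norm(b - c, axis=1)
        lb = np.linalg.norm(c - a, axis=1)
        lc = np.linalg.norm(a - b, axis=1)
        s = 0.5 * (la + lb + lc)
        area = self.tri_areas(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = 8.0 * (s - la) * (s - lb) * (s - lc) / (la * lb * lc)
        q = np.where(area <= 0, -1.0, q)
        return float(q.min())


# ---------------------------------------------------------------------------
# boundary resampling
# ---------------------------------------------------------------------------

def _resample_boundary(geometry: LVGeometry, spacing_mm: float,
                       refine_mm: Optional[float] = None,
                       refine_margin_mm: float = 6.0,
                       cap_mm: Optional[float] = None):
    """Resample the boundary loop, preserving vertices.

    Returns (points_mm, s_mm, edge_tags).  Spacing is reduced to
    ``refine_mm`` on the lesion outline and within ``refine_margin_mm`` of
    the septal crest, and capped everywhere at ``cap_mm`` (used to keep
    boundary segments short enough for wall-layer points to survive the
    Delaunay conformity requirement).
    """
    pts = geometry.points
    tags = geometry.edge_tags
    la = geometry.loop_arc()
    crest = geometry.crest_xy
    refine = refine_mm if refine_mm is not None else 0.5 * spacing_mm

    out_p, out_s, out_t = [], [], []
    P = len(pts)
    for i in range(P):
        a = pts[i]
        b = pts[(i + 1) % P]
        tag = tags[i]
        seg = np.linalg.norm(b - a)
        if seg < 1e-12:
            continue
        local = spacing_mm
        if cap_mm is not None:
            local = min(local, cap_mm)
        if tag == "lesion":
            local = min(local, refine)
        elif min(np.linalg.norm(a - crest), np.linalg.norm(b - crest)) \
                < refine_margin_mm:
            local = min(local, refine)
        nseg = max(1, int(np.ceil(seg / local)))
        f = np.arange(nseg) / nseg
        out_p.append(a[None, :] + f[:, None] * (b - a)[None, :])
        out_s.append(la[i] + f * seg)
        out_t.extend([tag] * nseg)
    return np.vstack(out_p), np.concatenate(out_s), \
        np.array(out_t, dtype=object)


# ---------------------------------------------------------------------------
# interior seeding + triangulation from an arbitrary closed boundary
# ---------------------------------------------------------------------------

def _triangulate(bpts: np.ndarray, btags: np.ndarray, bs: np.ndarray,
                 h: float, first: float, n_layers: int, growth: float,
                 cell_size: float, first_layer: float) -> TriMesh:
    """Mesh the interior of a closed CCW boundary polyline (units: metres)."""
    nb = len(bpts)
    poly = Polygon(bpts)
    if not poly.is_valid or poly.area <= 0:
        raise MeshError("boundary polygon is degenerate")

    # inward normals along the walk
    prev_idx = np.arange(nb) - 1
    nxt_idx = (np.arange(nb) + 1) % nb
    tan = bpts[nxt_idx] - bpts[prev_idx]
    tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-15)
    normal = np.column_stack([-tan[:, 1], tan[:, 0]])

    # layers along every boundary (open gaps included: their nodes need free
    # interior neighbours so the projection can absorb plug-profile mismatch)
    wall_nodes = np.ones(nb, bool)
    if growth != 1:
        offsets = first * (growth ** np.arange(1, n_layers + 1) - 1) \
            / (growth - 1)
    else:
        offsets = first * np.arange(1, n_layers + 1)

    btree = cKDTree(bpts)
    interior, spacings = [], []
    for off in offsets:
        if off > 0.8 * h:
            break
        q = bpts[wall_nodes] + off * normal[wall_nodes]
        inside = shapely.contains_xy(poly, q[:, 0], q[:, 1])
        q = q[inside]
        if len(q):
            d, _ = btree.query(q)
            q = q[d > 0.55 * off]
        if len(q):
            interior.append(q)
            spacings.append(np.full(len(q), max(off, first)))

    xmin, ymin, xmax, ymax = poly.bounds
    dy = h * np.sqrt(3) / 2
    rows, j = [], 0
    yy = ymin + 0.6 * dy
    while yy < ymax:
        xs = np.arange(xmin + (0.25 + 0.5 * (j % 2)) * h, xmax, h)
        rows.append(np.column_stack([xs, np.full_like(xs, yy)]))
        yy += dy
        j += 1
    if rows:
        bulk = np.vstack(rows)
        inner = poly.buffer(-0.7 * h)
        bulk = bulk[shapely.contains_xy(inner, bulk[:, 0], bulk[:, 1])]
        if len(bulk):
            d, _ = btree.query(bulk)
            bulk = bulk[d > 0.7 * h]
        if len(bulk):
            interior.append(bulk)
            spacings.append(np.full(len(bulk), h))

    if interior:
        interior = np.vstack(interior)
        spacings = np.concatenate(spacings)
        order = np.argsort(spacings)      # keep finer (layer) points first
        interior = interior[order]
        spacings = spacings[order]
        keep = np.ones(len(interior), bool)
        tree = cKDTree(interior)
        pairs = tree.query_pairs(r=float(spacings.max()),
                                 output_type="ndarray")
        if len(pairs):
            lim = 0.6 * np.minimum(spacings[pairs[:, 0]],
                                   spacings[pairs[:, 1]])
            dist = np.linalg.norm(interior[pairs[:, 0]]
                                  - interior[pairs[:, 1]], axis=1)
            for (i1, i2), dd, ll in zip(pairs, dist, lim):
                if dd < ll and keep[i1] and keep[i2]:
                    keep[max(i1, i2)] = False
        interior = interior[keep]
    else:
        interior = np.empty((0, 2))

    bedges = np.column_stack([np.arange(nb), (np.arange(nb) + 1) % nb])
    seg_len = np.linalg.norm(bpts[bedges[:, 1]] - bpts[bedges[:, 0]], axis=1)
    tris = None
    for clearance in (0.0, 1.2, 2.0, 3.0):
        cand = interior
        if len(cand) and clearance > 0:
            # drop interior points inside the (scaled) diametral circles of
            # boundary segments: guarantees segment recovery as clearance grows
            mid = 0.5 * (bpts[bedges[:, 0]] + bpts[bedges[:, 1]])
            mtree = cKDTree(mid)
            d, i_seg = mtree.query(cand)
            cand = cand[d > 0.5 * clearance * seg_len[i_seg]]
        allpts = np.vstack([bpts, cand])
        tri = Delaunay(allpts)
        cent = allpts[tri.simplices].mean(axis=1)
        inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        tris = tri.simplices[inside]
        # reject degenerate slivers (collinear boundary runs)
        pa = allpts[tris[:, 0]]
        pb = allpts[tris[:, 1]]
        pc = allpts[tris[:, 2]]
        ar2 = (pb[:, 0] - pa[:, 0]) * (pc[:, 1] - pa[:, 1]) \
            - (pb[:, 1] - pa[:, 1]) * (pc[:, 0] - pa[:, 0])
        tris = tris[np.abs(ar2) > 1e-7 * h * h]
        used = np.zeros(len(allpts), bool)
        used[tris.ravel()] = True
        if not used[:nb].all():
            tris = None
            continue
        edge_set = set()
        for t in tris:
            edge_set.add((min(t[0], t[1]), max(t[0], t[1])))
            edge_set.add((min(t[1], t[2]), max(t[1], t[2])))
            edge_set.add((min(t[0], t[2]), max(t[0], t[2])))
        if all((min(e[0], e[1]), max(e[0], e[1])) in edge_set
               for e in bedges):
            break
        tris = None
    if tris is None:
        raise MeshError("boundary segments not recovered by the "
                        "triangulation; reduce cell size contrast")

    new_id = -np.ones(len(allpts), int)
    new_id[used] = np.arange(used.sum())
    mesh = TriMesh(points=allpts[used], tris=new_id[tris],
                   bedges=new_id[bedges], btags=btags,
                   bnode_s={int(new_id[i]): float(bs[i]) for i in range(nb)},
                   cell_size=cell_size, first_layer=first_layer)
    areas = mesh.tri_areas()
    if (areas <= 0).any():  # pragma: no cover - Delaunay output is CCW
        bad = areas <= 0
        mesh.tris[bad] = mesh.tris[bad][:, ::-1]
    return mesh


def generate_mesh(geometry: LVGeometry, cell_size: float,
                  first_layer: float = 3e-4, n_layers: int = 3,
                  layer_growth: float = 1.6,
                  refine: Optional[float] = None) -> TriMesh:
    """Mesh the fluid polygon of a geometry.

    Parameters
    ----------
    geometry : LVGeometry
        Boundary in mm.
    cell_size : float
        Bulk target cell size in metres (e.g. 2e-3 desk scale; the reported
        production resolution was 175e-6 with a 20e-6 first layer).
    first_layer : float
        First wall-layer height in metres; layers grow geometrically by
        ``layer_growth`` toward the bulk size.
    refine : float, optional
        Local boundary spacing (metres) near the crest and on the lesion.

    Raises
    ------
    MeshError
        On degenerate polygons or loss of boundary conformity.
    """
    if cell_size <= 0 or first_layer <= 0:
        raise MeshError("cell_size and first_layer must be positive")
    if first_layer > cell_size:
        raise MeshError("first_layer must not exceed cell_size")
    bpts, bs, btags = _resample_boundary(
        geometry, cell_size / MM,
        (refine / MM) if refine is not None else None,
        cap_mm=max(2.5 * first_layer / MM, 0.3))
    return _triangulate(bpts * MM, btags, bs, cell_size, first_layer,
                        n_layers, layer_growth, cell_size, first_layer)


def remesh_interior(mesh: TriMesh, points: Optional[np.ndarray] = None,
                    n_layers: int = 3, layer_growth: float = 1.6) -> TriMesh:
    """Re-triangulate the interior keeping the current boundary nodes.

    Used when mesh motion degrades element quality: the (possibly displaced)
    boundary walk is retained node-for-node — preserving tags and the
    arc-coordinate map — and fresh interior points are seeded.
    """
    p = mesh.points if points is None else points
    order = mesh.bedges[:, 0]
    bpts = p[order]
    bs = np.array([mesh.bnode_s.get(int(i), np.nan) for i in order])
    return _triangulate(bpts, mesh.btags, bs, mesh.cell_size,
                        mesh.first_layer, n_layers, layer_growth,
                        mesh.cell_size, mesh.first_layer)


# ---------------------------------------------------------------------------
# structured meshes for verification problems
# ---------------------------------------------------------------------------

def structured_rect_mesh(lx: float, ly: float, nx: int, ny: int,
                         y_grading: Optional[np.ndarray] = None) -> TriMesh:
    """Structured crossed-triangle mesh of [0, lx] x [0, ly] (metres).

    Boundary tags are ``left``, ``right``, ``bottom``, ``top``.  An optional
    ``y_grading`` (monotone array in [0, 1] of length ny+1) redistributes the
    horizontal node lines, e.g. to refine near the walls.
    """
    xs = np.linspace(0, lx, nx + 1)
    if y_grading is not None:
        g = np.asarray(y_grading, float)
        if len(g) != ny + 1 or g[0] != 0 or g[-1] != 1:
            raise MeshError("y_grading must span [0, 1] with ny+1 entries")
        ys = ly * g
    else:
        ys = np.linspace(0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    points = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris += [[n00, n10, n11], [n00, n11, n01]]
            else:
                tris += [[n00, n10, n01], [n10, n11, n01]]
    tris = np.asarray(tris, int)

    bedges, btags = [], []
    for i in range(nx):                       # bottom, left to right
        bedges.append([nid(i, 0), nid(i + 1, 0)])
        btags.append("bottom")
    for j in range(ny):                       # right, upward
        bedges.append([nid(nx, j), nid(nx, j + 1)])
        btags.append("right")
    for i in range(nx, 0, -1):                # top, right to left
        bedges.append([nid(i, ny), nid(i - 1, ny)])
        btags.append("top")
    for j in range(ny, 0, -1):                # left, downward
        bedges.append([nid(0, j), nid(0, j - 1)])
        btags.append("left")

    return TriMesh(points=points, tris=tris,
                   bedges=np.asarray(bedges, int),
                   btags=np.array(btags, dtype=object),
                   cell_size=max(lx / nx, ly / ny))
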