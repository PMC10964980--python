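"""Labelled triangulated surface meshes and graph geodesics.

The mesh carries two edge sets:

* ``surface_edges`` — the triangle edges, used for region adjacency
  (connected components, zone extraction).
* ``graph_edges`` — the travel graph used by the activation solver and by
  geodesic neighbourhood queries.  On structured grids this is an extended
  stencil (axis edges, both cell diagonals, and gated knight moves), which
  bounds the worst-case direction-dependent metric error of graph shortest
  paths at 2.74%.  On arbitrary meshes it defaults to the triangle edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .config import CODE_LABELS, LABEL_CODES, MYOCARDIUM


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (N, 3) float, mm
    triangles: np.ndarray  # (M, 3) int
    vertex_label: np.ndarray  # (N,) int, 0 = conducting myocardium
    graph_edges: Optional[np.ndarray] = None  # (E, 2) int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.vertex_label = np.asarray(self.vertex_label, dtype=np.int64)
        if self.graph_edges is None:
            self.graph_edges = self.surface_edges.copy()
        else:
            self.graph_edges = np.asarray(self.graph_edges, dtype=np.int64)

    # ------------------------------------------------------------ basics
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def conducting(self) -> np.ndarray:
        return self.vertex_label == MYOCARDIUM

    @property
    def surface_edges(self) -> np.ndarray:
        """Unique undirected triangle edges, (E, 2) with i < j."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a = v[self.triangles[:, 1]] - v[self.triangles[:, 0]]
        b = v[self.triangles[:, 2]] - v[self.triangles[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of incident triangle areas)."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], areas / 3.0)
        return out

    def label_vertices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.vertex_label == LABEL_CODES[label])

    def has_label(self, label: str) -> bool:
        return bool(np.any(self.vertex_label == LABEL_CODES[label]))

    def boundary_of(self, label: str) -> np.ndarray:
        """Vertices of a structure that touch conducting tissue."""
        code = LABEL_CODES[label]
        e = self.surface_edges
        la, lb = self.vertex_label[e[:, 0]], self.vertex_label[e[:, 1]]
        out = np.concatenate(
            [
                e[(la == code) & (lb == MYOCARDIUM), 0],
                e[(lb == code) & (la == MYOCARDIUM), 1],
            ]
        )
        return np.unique(out)

    # ------------------------------------------------------------ graphs
    def _conducting_edges(self, edges: np.ndarray) -> np.ndarray:
        c = self.conducting
        return edges[c[edges[:, 0]] & c[edges[:, 1]]]

    def length_graph(self) -> sparse.csr_matrix:
        """Symmetric sparse graph of edge lengths over conducting tissue."""
        e = self._conducting_edges(self.graph_edges)
        w = self.edge_lengths(e)
        n = self.n_vertices
        g = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return g.tocsr()

    def time_graph(self, cv_field: np.ndarray) -> sparse.csr_matrix:
        """Edge traversal times: length / harmonic mean of endpoint CVs.

        A first-order eikonal approximation; cv_field is m/s (= mm/ms) per
        vertex and must be positive on conducting vertices.
        """
        cv_field = np.asarray(cv_field, dtype=float)
        e = self._conducting_edges(self.graph_edges)
        va, vb = cv_field[e[:, 0]], cv_field[e[:, 1]]
        if np.any(va <= 0) or np.any(vb <= 0):
            raise ValueError("cv_field must be > 0 on conducting vertices")
        w = self.edge_lengths(e) * 0.5 * (1.0 / va + 1.0 / vb)
        n = self.n_vertices
        g = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return g.tocsr()

    def geodesic_distances(
        self, sources: np.ndarray, limit: float = np.inf
    ) -> np.ndarray:
        """On-surface distances (mm) from each source vertex, inf beyond limit."""
        return csgraph.dijkstra(
            self.length_graph(), indices=np.atleast_1d(sources), limit=limit
        )

    # -------------------------------------------------------- validation
    def validate(self) -> None:
        if np.any(self.triangle_areas() <= 0):
            raise ValueError("mesh has degenerate (zero-area) triangles")
        valid_codes = {MYOCARDIUM, *CODE_LABELS.keys()}
        if not set(np.unique(self.vertex_label)) <= valid_codes:
            raise ValueError("mesh carries labels outside the structure enumeration")
        # every triangle edge shared by at most two triangles
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise ValueError("non-manifold edge shared by more than two triangles")
        # the conducting subgraph must be a single component
        c = self.conducting
        if c.sum() > 0:
            n_comp, lab = csgraph.connected_components(self.length_graph())
            comp_of_cond = lab[c]
            if len(np.unique(comp_of_cond)) > 1:
                raise ValueError("conducting subgraph is disconnected")

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.vertex_label.copy(),
            self.graph_edges.copy(),
            dict(self.meta),
        )


def grid_mesh(
    size_mm: tuple,
    spacing_mm: float = 1.0,
    kind: str = "sheet",
) -> SurfaceMesh:
    """Structured triangulated sheet (or cylinder) with the extended stencil.

    Vertices are laid out row-major: index = iy * nx + ix.  Cell diagonals
    alternate so both 45-degree directions are represented; knight-move
    edges are added later (after labelling) because they must be gated on
    conducting midpoints, see :func:`build_graph_edges`.
    """
    Lx, Ly = float(size_mm[0]), float(size_mm[1])
    h = float(spacing_mm)
    nx = int(round(Lx / h)) + 1
    ny = int(round(Ly / h)) + 1
    wrap = kind == "cylinder"
    if wrap:
        nx -= 1  # last column identical to first

    xs = np.arange(nx) * h
    ys = np.arange(ny) * h
    X, Y = np.meshgrid(xs, ys)  # shape (ny, nx)
    if wrap:
        radius = Lx / (2 * np.pi)
        theta = 2 * np.pi * X / Lx
        verts = np.column_stack(
            [radius * np.cos(theta).ravel(), radius * np.sin(theta).ravel(), Y.ravel()]
        )
    else:
        verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])

    def vid(ix, iy):
        return iy * nx + (ix % nx if wrap else ix)

    tris = []
    ncx = nx if wrap else nx - 1
    for iy in range(ny - 1):
        for ix in range(ncx):
            a = vid(ix, iy)
            b = vid(ix + 1, iy)
            c = vid(ix, iy + 1)
            d = vid(ix + 1, iy + 1)
            if (ix + iy) % 2 == 0:
                tris += [[a, b, d], [a, d, c]]
            else:
                tris += [[a, b, c], [b, d, c]]

    mesh = SurfaceMesh(
        verts,
        np.array(tris),
        np.zeros(len(verts), dtype=np.int64),
        meta={"kind": kind, "nx": nx, "ny": ny, "spacing_mm": h, "size_mm": (Lx, Ly)},
    )
    mesh.meta["unrolled_xy"] = np.column_stack([X.ravel(), Y.ravel()])
    return mesh


def build_graph_edges(mesh: SurfaceMesh) -> None:
    """(Re)build the extended travel stencil, gating on the current labels.

    Edge families: axis (length h), both cell diagonals (h*sqrt(2)) and
    knight moves (h*sqrt(5)).  A knight edge is kept only when the two
    lattice vertices nearest its midpoint are conducting, so the long edges
    cannot tunnel through one-vertex-thick non-conducting barriers.
    """
    nx, ny = mesh.meta["nx"], mesh.meta["ny"]
    wrap = mesh.meta["kind"] == "cylinder"
    cond = mesh.conducting.reshape(ny, nx)

    IX, IY = np.meshgrid(np.arange(nx), np.arange(ny))

    def vid(ix, iy):
        return iy * nx + (ix % nx)

    edges = []

    def add(dx, dy, gates=()):
        ix, iy = IX.ravel(), IY.ravel()
        jx, jy = ix + dx, iy + dy
        ok = (jy >= 0) & (jy < ny)
        if not wrap:
            ok &= (jx >= 0) & (jx < nx)
        for gx, gy in gates:
            kx, ky = ix + gx, iy + gy
            okg = (ky >= 0) & (ky < ny)
            if not wrap:
                okg &= (kx >= 0) & (kx < nx)
            gate_ok = np.zeros_like(ok)
            idx = okg
            gate_ok[idx] = cond[ky[idx] % ny, kx[idx] % nx]
            ok &= gate_ok
        i = vid(ix[ok], iy[ok])
        j = vid(jx[ok], jy[ok])
        edges.append(np.column_stack([i, j]))

    # axis + both diagonals (no extra gating beyond conducting endpoints,
    # applied downstream in the graph builders)
    add(1, 0)
    add(0, 1)
    add(1, 1)
    add(1, -1)
    # knight moves, gated on midpoint vertices
    add(2, 1, gates=[(1, 0), (1, 1)])
    add(2, -1, gates=[(1, 0), (1, -1)])
    add(1, 2, gates=[(0, 1), (1, 1)])
    add(1, -2, gates=[(0, -1), (1, -1)])

    e = np.concatenate(edges)
    e = e[e[:, 0] != e[:, 1]]
    e.sort(axis=1)
    mesh.graph_edges = np.unique(e, axis=0)


def label_rect(mesh: SurfaceMesh, label: str, rect: tuple) -> None:
    """Label vertices inside an axis-aligned rectangle (unrolled mm coords)."""
    xy = mesh.meta.get("unrolled_xy")
    if xy is None:
        xy = mesh.vertices[:, :2]
    x0, y0, x1, y1 = rect
    eps = 1e-9
    inside = (
        (xy[:, 0] >= x0 - eps)
        & (xy[:, 0] <= x1 + eps)
        & (xy[:, 1] >= y0 - eps)
        & (xy[:, 1] <= y1 + eps)
    )
    mesh.vertex_label[inside] = LABEL_CODES[label]
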