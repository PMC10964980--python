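"""Propagation features of the isochronal map.

Deceleration zones (isochronal crowding: more than three isochrones within
a 1 cm radius), extreme conduction slowing (thin crowding plus continuous
fractionated activity), lines of conduction block (split potentials with an
activation gap and reversed activation on the far side), and wave-front
collisions (simultaneous arrival of opposing fronts).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .ilam import IsochronalMap


@dataclass
class FeatureThresholds:
    dz_radius_mm: float = 10.0  # "1 cm radius", read literally as a radius
    dz_min_isochrones: int = 4  # strictly more than 3 distinct isochrones
    block_gap_ms: float = 20.0
    min_zone_area_mm2: float = 10.0
    extreme_min_isochrones: int = 6
    extreme_fraction_fractionated: float = 0.5
    metric: str = "geodesic"  # or "euclidean" (flat-sheet testing)

    def __post_init__(self):
        if self.dz_radius_mm <= 0 or self.dz_min_isochrones <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DecelerationZone:
    member_vertices: np.ndarray
    peak_isochrone_count: int
    centroid: np.ndarray  # (3,) mm
    area_mm2: float
    overlapping_ai: Optional[str] = None
    extreme: bool = False


@dataclass
class BlockLine:
    vertices: np.ndarray  # polyline vertex ids (ordered along the line)
    mean_gap_ms: float
    reversal_confirmed: bool


# --------------------------------------------------------------------------
# isochronal crowding
# --------------------------------------------------------------------------
def _neighbour_distances(im: IsochronalMap, radius: float, metric: str,
                         sources: np.ndarray) -> np.ndarray:
    if metric == "euclidean":
        tree = cKDTree(im.mesh.vertices)
        out = np.full((len(sources), im.mesh.n_vertices), np.inf)
        for r, s in enumerate(sources):
            idx = tree.query_ball_point(im.mesh.vertices[s], radius)
            out[r, idx] = np.linalg.norm(
                im.mesh.vertices[idx] - im.mesh.vertices[s], axis=1
            )
        return out
    return csgraph.dijkstra(im.mesh.length_graph(), indices=sources, limit=radius)


def count_isochrones_in_radius(
    im: IsochronalMap,
    vertex: int,
    radius_mm: float = 10.0,
    metric: str = "geodesic",
) -> int:
    """Distinct isochrone indices among mapped vertices within the radius."""
    if im.iso_index[vertex] < 0:
        raise ValueError(f"vertex {vertex} is not mapped")
    d = _neighbour_distances(im, radius_mm, metric, np.array([vertex]))[0]
    inside = np.isfinite(d) & (d <= radius_mm) & im.mapped
    return int(len(np.unique(im.iso_index[inside])))


def crowding_counts(
    im: IsochronalMap, thr: FeatureThresholds, chunk: int = 512
) -> np.ndarray:
    """Per-vertex isochrone counts within the DZ radius (-1 where unmapped)."""
    mapped_idx = np.flatnonzero(im.mapped)
    counts = np.full(im.mesh.n_vertices, -1, dtype=np.int64)
    for s in range(0, len(mapped_idx), chunk):
        src = mapped_idx[s : s + chunk]
        d = _neighbour_distances(im, thr.dz_radius_mm, thr.metric, src)
        inside = np.isfinite(d) & (d <= thr.dz_radius_mm) & im.mapped[None, :]
        iso = im.iso_index
        for r, v in enumerate(src):
            counts[v] = len(np.unique(iso[inside[r]]))
    return counts


def detect_deceleration_zones(
    im: IsochronalMap, thr: Optional[FeatureThresholds] = None
) -> list:
    """Connected regions whose vertices see >3 isochrones within 1 cm.

    Regions are connected components of super-threshold vertices over the
    triangle adjacency; components below ``min_zone_area_mm2`` are dropped
    as speckle.  Zones come back sorted by peak count, then area.
    """
    thr = thr or FeatureThresholds()
    counts = crowding_counts(im, thr)
    mask = counts >= thr.dz_min_isochrones
    if not mask.any():
        return []

    e = im.mesh.surface_edges
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    n = im.mesh.n_vertices
    g = sparse.coo_matrix(
        (np.ones(keep.sum()), (e[keep, 0], e[keep, 1])), shape=(n, n)
    )
    _, comp = csgraph.connected_components(g, directed=False)
    areas = im.mesh.vertex_areas()

    zones = []
    for c in np.unique(comp[mask]):
        members = np.flatnonzero(mask & (comp == c))
        area = float(areas[members].sum())
        if area < thr.min_zone_area_mm2:
            continue
        zones.append(
            DecelerationZone(
                member_vertices=members,
                peak_isochrone_count=int(counts[members].max()),
                centroid=im.mesh.vertices[members].mean(axis=0),
                area_mm2=area,
            )
        )
    zones.sort(key=lambda z: (-z.peak_isochrone_count, -z.area_mm2))
    return zones


def flag_extreme_slowing(
    dz: DecelerationZone,
    points: pd.DataFrame,
    thr: Optional[FeatureThresholds] = None,
) -> bool:
    """Thinner crowding plus continuous fractionated local activity.

    True when the zone's peak count reaches ``extreme_min_isochrones`` AND a
    majority of the mapping sites inside the zone are fractionated.
    """
    thr = thr or FeatureThresholds()
    dz.extreme = False
    if dz.peak_isochrone_count >= thr.extreme_min_isochrones and "vertex" in points:
        members = set(int(v) for v in dz.member_vertices)
        inside = points[
            points["used"] & points["vertex"].map(lambda v: int(v) in members)
        ]
        if len(inside) > 0:
            frac = float(inside["fractionated"].mean())
            dz.extreme = frac > thr.extreme_fraction_fractionated
    return dz.extreme


# --------------------------------------------------------------------------
# lines of block
# --------------------------------------------------------------------------
def detect_block_lines(
    im: IsochronalMap,
    points: pd.DataFrame,
    thr: Optional[FeatureThresholds] = None,
    split_site_radius_mm: float = 3.0,
) -> list:
    """Chains of edges with a super-bin LAT jump flanked by split potentials.

    Candidate edges have |dLAT| greater than one isochrone bin width and a
    split-potential site within ``split_site_radius_mm`` of an endpoint;
    connected candidates are chained into polylines.  Reversal is confirmed
    when the local LAT gradients on the two sides point in opposite
    directions (negative inner product).
    """
    thr = thr or FeatureThresholds()
    lat = im.vertex_lat
    e = im.mesh.surface_edges
    both = im.mapped[e[:, 0]] & im.mapped[e[:, 1]]
    dlat = np.abs(lat[e[:, 0]] - lat[e[:, 1]])
    jump = both & (dlat > im.bin_width_ms)
    if not jump.any():
        return []

    split_pts = points[points["used"] & points["split"]]
    if len(split_pts) == 0:
        return []
    stree = cKDTree(split_pts[["x", "y", "z"]].to_numpy(dtype=float))

    cand = np.flatnonzero(jump)
    near_split = np.zeros(len(cand), dtype=bool)
    for k, ei in enumerate(cand):
        for v in e[ei]:
            d, _ = stree.query(im.mesh.vertices[v])
            if d <= split_site_radius_mm:
                near_split[k] = True
                break
    cand = cand[near_split]
    if len(cand) == 0:
        return []

    # chain candidate edges that share vertices
    n = im.mesh.n_vertices
    g = sparse.coo_matrix(
        (np.ones(len(cand)), (e[cand, 0], e[cand, 1])), shape=(n, n)
    )
    ncomp, comp = csgraph.connected_components(g, directed=False)
    line_vertices = np.unique(e[cand].ravel())

    lines = []
    for c in np.unique(comp[line_vertices]):
        members = line_vertices[comp[line_vertices] == c]
        if len(members) < 2:
            continue
        edges_c = cand[
            np.isin(e[cand, 0], members) & np.isin(e[cand, 1], members)
        ]
        lo_side = np.where(
            lat[e[edges_c, 0]] < lat[e[edges_c, 1]], e[edges_c, 0], e[edges_c, 1]
        )
        hi_side = np.where(
            lat[e[edges_c, 0]] < lat[e[edges_c, 1]], e[edges_c, 1], e[edges_c, 0]
        )
        g_lo = _mean_gradient(im, np.unique(lo_side))
        g_hi = _mean_gradient(im, np.unique(hi_side))
        reversal = bool(np.dot(g_lo, g_hi) < 0)

        gaps = []
        for v in members:
            idx = stree.query_ball_point(im.mesh.vertices[v], split_site_radius_mm)
            gaps.extend(split_pts["gap_ms"].to_numpy()[idx])
        ordered = _order_polyline(im.mesh.vertices[members], members)
        lines.append(
            BlockLine(
                vertices=ordered,
                mean_gap_ms=float(np.mean(gaps)) if gaps else np.nan,
                reversal_confirmed=reversal,
            )
        )
    lines.sort(key=lambda b: -len(b.vertices))
    return lines


def _mean_gradient(im: IsochronalMap, verts: np.ndarray,
                   radius: float = 3.0) -> np.ndarray:
    """Average least-squares LAT gradient around vertices, same-side only."""
    lat = im.vertex_lat
    tree = cKDTree(im.mesh.vertices)
    grads = []
    for v in verts:
        idx = np.array(tree.query_ball_point(im.mesh.vertices[v], radius))
        idx = idx[
            im.mapped[idx] & (np.abs(lat[idx] - lat[v]) <= im.bin_width_ms)
        ]
        if len(idx) < 3:
            continue
        X = im.mesh.vertices[idx] - im.mesh.vertices[v]
        y = lat[idx] - lat[v]
        g, *_ = np.linalg.lstsq(X[:, :2], y, rcond=None)
        grads.append(g)
    if not grads:
        return np.zeros(2)
    return np.mean(grads, axis=0)


def _order_polyline(positions: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Order line vertices along their principal axis."""
    centred = positions - positions.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    s = centred @ vt[0]
    return members[np.argsort(s)]


# --------------------------------------------------------------------------
# wave-front collision
# --------------------------------------------------------------------------
def detect_collisions(
    im: IsochronalMap, drop_ms: float = 1.0, min_opposition: float = -0.9,
    min_size: int = 3,
) -> list:
    """Vertex sets where two opposing wave fronts arrive simultaneously.

    A collision vertex is a local LAT maximum along an opposing pair of
    approach directions: two neighbours on (near-)opposite sides (inner
    product of directions below ``min_opposition``) both activate earlier
    by at least ``drop_ms``.  Returns a list of connected vertex arrays.
    """
    lat = im.vertex_lat
    e = im.mesh.graph_edges
    both = im.mapped[e[:, 0]] & im.mapped[e[:, 1]]
    e = e[both]

    n = im.mesh.n_vertices
    nbr = [[] for _ in range(n)]
    for a, b in e:
        nbr[a].append(b)
        nbr[b].append(a)

    hits = []
    for v in np.flatnonzero(im.mapped):
        nb = np.array(nbr[v], dtype=np.int64)
        if len(nb) < 2:
            continue
        dl = lat[nb] - lat[v]
        lower = nb[dl <= -drop_ms]
        if len(lower) < 2:
            continue
        dirs = im.mesh.vertices[lower] - im.mesh.vertices[v]
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        dots = dirs @ dirs.T
        if dots.min() < min_opposition:
            hits.append(v)

    if not hits:
        return []
    hits = np.array(hits)
    mask = np.zeros(n, dtype=bool)
    mask[hits] = True
    se = im.mesh.surface_edges
    keep = mask[se[:, 0]] & mask[se[:, 1]]
    g = sparse.coo_matrix(
        (np.ones(keep.sum()), (se[keep, 0], se[keep, 1])), shape=(n, n)
    )
    _, comp = csgraph.connected_components(g, directed=False)
    sets = [hits[comp[hits] == c] for c in np.unique(comp[hits])]
    return [s for s in sets if len(s) >= min_size]
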