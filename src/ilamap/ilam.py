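"""Isochronal late activation map construction.

Annotated mapping points are projected onto the mesh, local activation
times are interpolated over conducting vertices (inverse-distance weighting
within a geodesic fill radius), and the mapped activation range is
partitioned into eight equal-duration isochrones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

N_ISOCHRONES = 8


@dataclass
class ActivationMap:
    """Annotated point cloud on a mesh, optionally with interpolated LATs."""

    mesh: SurfaceMesh
    points: pd.DataFrame  # site_id, x, y, z, lat_ms, voltage_mV, split,
    #                       gap_ms, n_deflections, fractionated, used[, vertex]
    vertex_lat: Optional[np.ndarray] = None
    rhythm: str = "paced"

    @property
    def n_acquired(self) -> int:
        return len(self.points)

    @property
    def n_used(self) -> int:
        return int(self.points["used"].sum())

    def used_point_rate(self) -> float:
        """Used/acquired rate in percent, to one decimal (as reported)."""
        return used_point_rate(self.n_used, self.n_acquired)


@dataclass
class IsochronalMap:
    mesh: SurfaceMesh
    vertex_lat: np.ndarray  # NaN where unmapped
    bin_edges: np.ndarray  # 9 increasing values (ms)
    iso_index: np.ndarray  # int in 0..7, -1 where unmapped
    total_activation_time: float  # LATmax - LATmin (ms)

    @property
    def mapped(self) -> np.ndarray:
        return self.iso_index >= 0

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def summary(self) -> dict:
        return {
            "n_isochrones": N_ISOCHRONES,
            "bin_edges_ms": [float(b) for b in self.bin_edges],
            "total_activation_time_ms": float(self.total_activation_time),
            "n_mapped_vertices": int(self.mapped.sum()),
        }


def used_point_rate(n_used: int, n_acquired: int) -> float:
    """Percentage of acquired points used in the map, to one decimal."""
    if n_acquired <= 0:
        raise ValueError("no acquired points")
    return round(100.0 * n_used / n_acquired, 1)


def project_points(amap: ActivationMap, max_distance_mm: float = 5.0) -> ActivationMap:
    """Assign each used point to its nearest mesh vertex.

    Points farther than ``max_distance_mm`` from every vertex are flagged
    unused (vertex = -1).  Euclidean projection; the fill radius downstream
    is geodesic.
    """
    pts = amap.points
    if not pts["used"].any():
        raise ValueError("no used points to project")
    pos = pts[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(amap.mesh.vertices)
    dist, vert = tree.query(pos)
    vert = vert.astype(np.int64)
    too_far = dist > max_distance_mm
    vert[too_far] = -1
    pts = pts.copy()
    pts["vertex"] = vert
    pts["projection_mm"] = dist
    pts.loc[too_far, "used"] = False
    return ActivationMap(amap.mesh, pts, amap.vertex_lat, amap.rhythm)


def interpolate_lat(
    amap: ActivationMap, fill_radius_mm: float = 5.0, power: float = 2.0
) -> ActivationMap:
    """Inverse-distance-weighted LAT over conducting vertices.

    Distances are geodesic (graph shortest paths on the conducting surface).
    Vertices with no contributing point inside the fill radius stay
    unmapped (NaN); point-bearing vertices reproduce their point LAT
    exactly (coincident points average).
    """
    pts = amap.points
    mesh = amap.mesh
    if "vertex" not in pts:
        raise ValueError("points are not projected; run project_points first")
    ok = pts["used"] & (pts["vertex"] >= 0)
    ok &= pts["vertex"].map(lambda v: bool(mesh.conducting[int(v)]) if v >= 0 else False)
    src = pts.loc[ok, "vertex"].to_numpy(dtype=np.int64)
    lat_p = pts.loc[ok, "lat_ms"].to_numpy(dtype=float)
    if len(src) == 0:
        raise ValueError("no used points on conducting vertices")

    # collapse coincident points
    uniq, inv = np.unique(src, return_inverse=True)
    sums = np.bincount(inv, weights=lat_p)
    vals = sums / np.bincount(inv)

    d = csgraph.dijkstra(mesh.length_graph(), indices=uniq, limit=fill_radius_mm)
    n = mesh.n_vertices
    out = np.full(n, np.nan)

    with np.errstate(divide="ignore"):
        w = np.where(np.isfinite(d), 1.0 / np.maximum(d, 1e-12) ** power, 0.0)
    wsum = w.sum(axis=0)
    covered = wsum > 0
    out[covered] = (w[:, covered] * vals[:, None]).sum(axis=0) / wsum[covered]
    # exact at point-bearing vertices
    out[uniq] = vals
    out[~mesh.conducting] = np.nan
    return ActivationMap(mesh, pts, out, amap.rhythm)


def build_ilam(amap: ActivationMap) -> IsochronalMap:
    """Partition the mapped LAT range into eight equal isochrones.

    The last bin is right-closed (LATmax gets index 7), the others
    right-open.  Raises on a degenerate activation range.
    """
    if amap.vertex_lat is None:
        raise ValueError("no interpolated LAT field; run interpolate_lat first")
    lat = np.asarray(amap.vertex_lat, dtype=float)
    mapped = np.isfinite(lat)
    if mapped.sum() < 2:
        raise ValueError("need at least two mapped vertices")
    lo, hi = float(np.nanmin(lat)), float(np.nanmax(lat))
    if hi <= lo:
        raise ValueError("degenerate activation range (all LATs equal)")
    edges = np.linspace(lo, hi, N_ISOCHRONES + 1)
    width = (hi - lo) / N_ISOCHRONES
    idx = np.full(len(lat), -1, dtype=np.int64)
    idx[mapped] = np.minimum(
        ((lat[mapped] - lo) / width).astype(np.int64), N_ISOCHRONES - 1
    )
    return IsochronalMap(
        mesh=amap.mesh,
        vertex_lat=lat,
        bin_edges=edges,
        iso_index=idx,
        total_activation_time=hi - lo,
    )
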