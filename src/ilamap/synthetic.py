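"""Synthetic electroanatomical mapping studies.

This module is the stand-in for the patient maps: it generates labelled
right-ventricular-like surfaces with non-conducting structures (annuli,
patches, incisions, scar), simulates first-arrival activation with
region-dependent conduction velocity, samples grid-catheter-like mapping
sites and synthesizes multi-deflection bipolar electrograms whose last
deflection encodes the true local activation time.

The default study conditions are chosen once from the physics of the
isochronal display (see docs/methods.md): corridors are 18 mm long (the
length of the worked-example isthmus), background CV is 0.6 m/s, and the
sheet is sized so the non-corridor share of the total activation time is
about 100 ms — the regime in which the ">3 isochrones within 1 cm" crowding
criterion corresponds to a corridor CV near 0.5 m/s.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .config import (
    AI_BOUNDS,
    CorridorSpec,
    EgmConfig,
    GeometryConfig,
    ScenarioConfig,
    StructureSpec,
    substream,
)
from .egm import BipoleSet, Electrogram
from .mesh import SurfaceMesh, build_graph_edges, grid_mesh, label_rect


@dataclass
class GroundTruth:
    """Recovery targets for the synthetic study."""

    lat_ms: np.ndarray  # per-vertex true LAT, NaN on non-conducting/unreached
    cv_field: np.ndarray  # per-vertex CV (m/s)
    corridors: list = field(default_factory=list)  # dicts per corridor
    block_vertices: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64)
    )

    def corridor_sc(self) -> dict:
        """Planted slow-conduction flag per corridor (CV < 0.5 m/s)."""
        return {c["ai_type"]: c["planted_cv"] < 0.5 for c in self.corridors}


# --------------------------------------------------------------------------
# surface generation
# --------------------------------------------------------------------------
def generate_surface(config: ScenarioConfig) -> SurfaceMesh:
    """Build the labelled mesh for a scenario.

    Deterministic: geometry and labels depend only on the config.  Raises if
    a requested corridor has been destroyed by overlapping structures.
    """
    config.validate()
    mesh = grid_mesh(config.geometry.size_mm, config.geometry.spacing_mm,
                     config.geometry.kind)
    for s in config.structures:
        label_rect(mesh, s.label, s.rect)
    build_graph_edges(mesh)
    mesh.validate()

    for c in config.corridors:
        la, lb = AI_BOUNDS[c.ai_type]
        if not (mesh.has_label(la) and mesh.has_label(lb)):
            raise ValueError(
                f"corridor {c.ai_type} requested but structures "
                f"{la}/{lb} are not both present"
            )
        w = measure_corridor_width(mesh, c.ai_type)
        if not np.isfinite(w) or abs(w - c.width_mm) > 0.1 * c.width_mm + 1e-9:
            raise ValueError(
                f"corridor {c.ai_type}: measured width {w:.2f} mm is not "
                f"within 10% of requested {c.width_mm:.2f} mm "
                "(overlapping structures?)"
            )
    return mesh


def measure_corridor_width(mesh: SurfaceMesh, ai_type: str) -> float:
    """Minimal distance between the two bounding structure boundaries."""
    la, lb = AI_BOUNDS[ai_type]
    ba, bb = mesh.boundary_of(la), mesh.boundary_of(lb)
    if len(ba) == 0 or len(bb) == 0:
        return np.inf
    pa, pb = mesh.vertices[ba], mesh.vertices[bb]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return float(d.min())


def build_cv_field(config: ScenarioConfig, mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex conduction velocity: background + planted corridor CVs."""
    cv = np.full(mesh.n_vertices, config.background_cv)
    xy = mesh.meta.get("unrolled_xy", mesh.vertices[:, :2])
    for c in config.corridors:
        rect = _corridor_rect(config, c.ai_type)
        x0, y0, x1, y1 = rect
        inside = (
            (xy[:, 0] >= x0) & (xy[:, 0] <= x1)
            & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
        )
        cv[inside & mesh.conducting] = c.planted_cv
    cv[~mesh.conducting] = np.nan
    return cv


def _corridor_rect(config: ScenarioConfig, ai_type: str):
    """Gap rectangle between the two bounding structures of a corridor."""
    la, lb = AI_BOUNDS[ai_type]
    ra = next(s.rect for s in config.structures if s.label == la)
    rb = next(s.rect for s in config.structures if s.label == lb)
    # overlap in x, gap in y (the builders lay corridors out horizontally)
    x0 = max(ra[0], rb[0])
    x1 = min(ra[2], rb[2])
    if ra[1] > rb[3]:  # a above b
        y0, y1 = rb[3], ra[1]
    else:
        y0, y1 = ra[3], rb[1]
    return (x0, y0, x1, y1)


# --------------------------------------------------------------------------
# scenario builders (the study conditions)
# --------------------------------------------------------------------------
CORRIDOR_LENGTH_MM = 18.0  # worked-example isthmus length


def corridor_scenario(
    planted_cv: float,
    ai_type: str = "AI3",
    width_mm: float = 12.0,
    seed: int = 0,
    point_density: float = 20.0,
    noise_mV: float = 0.0,
    spacing_mm: float = 1.0,
) -> ScenarioConfig:
    """Single-corridor study: two structure bands flanking an 18 mm corridor.

    The sheet is 136 x 50 mm with the pacing source on the left edge; the
    only conducting path from the left to the right compartment is the
    corridor, so the activation delay across it is governed by the planted
    CV.  Background tissue conducts at 1.2 m/s (the non-slow isthmus median)
    and the background share of the total activation time is ~110 ms, the
    regime in which isochronal crowding (>3 isochrones per cm radius)
    switches on at a corridor CV near 0.5 m/s.
    """
    Lx, Ly = 136.0, 50.0
    x0, x1 = 59.0, 59.0 + CORRIDOR_LENGTH_MM
    yc = Ly / 2.0
    la, lb = AI_BOUNDS[ai_type]
    upper = StructureSpec(la, (x0, yc + width_mm / 2.0, x1, Ly))
    lower = StructureSpec(lb, (x0, 0.0, x1, yc - width_mm / 2.0))
    egm = EgmConfig(noise_mV=noise_mV)
    return ScenarioConfig(
        seed=seed,
        geometry=GeometryConfig("sheet", (Lx, Ly), spacing_mm),
        structures=[upper, lower],
        corridors=[CorridorSpec(ai_type, width_mm, planted_cv)],
        background_cv=1.2,
        pacing_sources=[((1.0, yc), 0.0)],
        point_density=point_density,
        egm=egm,
        rhythm="paced",
    )


def default_rtf_scenario(seed: int = 0, noise_mV: float = 0.0) -> ScenarioConfig:
    """Four-isthmus repaired-TOF-like map on a 110 x 80 mm opened-RV sheet.

    Tricuspid and pulmonary annuli are full-width bands at the sheet edges;
    an RV incision and a VSD patch stand between them, leaving the four
    classical corridors AI1-AI4.  Corridor widths follow the cohort medians
    (AI1 28, AI2 7, AI3 11, AI4 15 mm); AI3 carries the slow corridor.
    """
    Lx, Ly = 110.0, 80.0
    ta_top, pa_bot = 10.0, 70.0
    inc = (34.0, ta_top + 28.0, 52.0, pa_bot - 7.0)
    vsd = (66.0, ta_top + 15.0, 84.0, pa_bot - 11.0)
    structures = [
        StructureSpec("tricuspid_annulus", (0.0, 0.0, Lx, ta_top)),
        StructureSpec("pulmonary_annulus", (0.0, pa_bot, Lx, Ly)),
        StructureSpec("rv_incision", inc),
        StructureSpec("vsd_patch", vsd),
        StructureSpec("scar_patch", (8.0, 52.0, 20.0, 64.0)),
    ]
    corridors = [
        CorridorSpec("AI1", 28.0, 1.25),
        CorridorSpec("AI2", 7.0, 0.4),
        CorridorSpec("AI3", 11.0, 0.15),
        CorridorSpec("AI4", 15.0, 0.8),
    ]
    return ScenarioConfig(
        seed=seed,
        geometry=GeometryConfig("sheet", (Lx, Ly), 1.0),
        structures=structures,
        corridors=corridors,
        background_cv=0.8,
        pacing_sources=[((2.0, 40.0), 0.0)],
        point_density=20.0,
        egm=EgmConfig(noise_mV=noise_mV),
        rhythm="paced",
    )


def ablation_demo_scenario(seed: int = 0, detour: bool = True) -> ScenarioConfig:
    """Corridor between two scar patches, with an optional detour channel.

    Used to emulate the post-ablation remap: transecting the corridor while a
    detour exists reverses the activation direction distal to the line.
    """
    Lx, Ly = 70.0, 40.0
    top_y1 = Ly if not detour else 36.0
    structures = [
        StructureSpec("scar_patch", (20.0, 0.0, 50.0, 14.0)),
        StructureSpec("rv_incision", (20.0, 26.0, 50.0, top_y1)),
    ]
    return ScenarioConfig(
        seed=seed,
        geometry=GeometryConfig("sheet", (Lx, Ly), 1.0),
        structures=structures,
        corridors=[],
        background_cv=0.6,
        pacing_sources=[((1.0, 20.0), 0.0)],
        point_density=20.0,
        egm=EgmConfig(noise_mV=0.0),
        rhythm="paced",
    )


# --------------------------------------------------------------------------
# activation simulation
# --------------------------------------------------------------------------
def simulate_activation(
    mesh: SurfaceMesh,
    cv_field: np.ndarray,
    sources: Sequence,
) -> np.ndarray:
    """First-arrival local activation times (ms) per vertex.

    ``sources`` is a sequence of ``((x, y[, z]), onset_ms)`` positions or
    ``(vertex_index, onset_ms)`` pairs.  Non-conducting vertices get NaN;
    conducting vertices unreachable from every source are NaN with a warning.
    """
    cv_field = np.asarray(cv_field, dtype=float)
    cond = mesh.conducting
    src_idx, src_t0 = [], []
    for loc, t0 in sources:
        if np.isscalar(loc):
            vi = int(loc)
        else:
            loc = np.asarray(loc, dtype=float)
            if loc.size == 2:
                loc = np.r_[loc, 0.0]
            vi = int(np.argmin(np.linalg.norm(mesh.vertices - loc, axis=1)))
        if not cond[vi]:
            raise ValueError(f"pacing source at vertex {vi} is non-conducting")
        src_idx.append(vi)
        src_t0.append(float(t0))
    if not src_idx:
        raise ValueError("at least one pacing source is required")

    safe_cv = np.where(cond & np.isfinite(cv_field), cv_field, 1.0)
    g = mesh.time_graph(safe_cv)
    d = csgraph.dijkstra(g, indices=src_idx)
    lat = np.min(d + np.asarray(src_t0)[:, None], axis=0)

    lat[~cond] = np.nan
    unreached = cond & ~np.isfinite(lat)
    if unreached.any():
        warnings.warn(
            f"{int(unreached.sum())} conducting vertices unreachable from the "
            "pacing sources; flagged unmapped",
            stacklevel=2,
        )
        lat[unreached] = np.nan
    return lat


def ground_truth(config: ScenarioConfig, mesh: SurfaceMesh) -> GroundTruth:
    cv = build_cv_field(config, mesh)
    lat = simulate_activation(mesh, cv, config.pacing_sources)
    corridors = [
        {
            "ai_type": c.ai_type,
            "planted_cv": c.planted_cv,
            "width_mm": c.width_mm,
            "sc_true": c.planted_cv < 0.5,
        }
        for c in config.corridors
    ]
    return GroundTruth(lat_ms=lat, cv_field=cv, corridors=corridors)


# --------------------------------------------------------------------------
# ablation-line editing
# --------------------------------------------------------------------------
def apply_ablation_line(mesh: SurfaceMesh, polyline: Sequence) -> SurfaceMesh:
    """Return a mesh with every conducting graph edge crossing the line cut.

    The polyline is a sequence of (x, y) points in the sheet plane; only
    flat-sheet geometry is supported.  An empty polyline is the identity; a
    polyline that crosses no conducting edge is a no-op with a warning.
    """
    polyline = np.asarray(polyline, dtype=float).reshape(-1, 2)
    if len(polyline) < 2:
        return mesh.copy()
    if mesh.meta.get("kind") == "cylinder":
        raise ValueError("ablation-line editing is supported on sheet geometry only")

    e = mesh.graph_edges
    p = mesh.vertices[e[:, 0], :2]
    q = mesh.vertices[e[:, 1], :2]
    cut = np.zeros(len(e), dtype=bool)
    for a, b in zip(polyline[:-1], polyline[1:]):
        cut |= _segments_intersect(p, q, a, b)

    cond = mesh.conducting
    cut_conducting = cut & cond[e[:, 0]] & cond[e[:, 1]]
    if not cut_conducting.any():
        warnings.warn("ablation line crosses no conducting edge; mesh unchanged",
                      stacklevel=2)
        return mesh.copy()

    out = mesh.copy()
    out.graph_edges = e[~cut]
    out.meta = dict(out.meta)
    lines = list(out.meta.get("ablation_lines", []))
    lines.append(polyline.tolist())
    out.meta["ablation_lines"] = lines
    return out


def _segments_intersect(p, q, a, b):
    """Vectorized proper/improper intersection of edges (p,q) with segment ab."""
    def cross(o, u, v):
        return (u[..., 0] - o[..., 0]) * (v[..., 1] - o[..., 1]) - (
            u[..., 1] - o[..., 1]
        ) * (v[..., 0] - o[..., 0])

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d1 = cross(a[None, :], b[None, :], p)
    d2 = cross(a[None, :], b[None, :], q)
    d3 = cross(p, q, a[None, :])
    d4 = cross(p, q, b[None, :])
    return ((d1 * d2) < 0) & ((d3 * d4) < 0)


# --------------------------------------------------------------------------
# mapping-site sampling and electrogram synthesis
# --------------------------------------------------------------------------
def sample_sites(config: ScenarioConfig, mesh: SurfaceMesh) -> np.ndarray:
    """Random acquisition sites, ``point_density`` per cm^2 of sheet area."""
    rng = substream(config.seed, "sites")
    Lx, Ly = mesh.meta["size_mm"]
    n = int(round(config.point_density * (Lx * Ly) / 100.0))
    xy = rng.uniform([0.0, 0.0], [Lx, Ly], size=(n, 2))
    return np.column_stack([xy, np.zeros(n)])


def synthesize_electrograms(
    mesh: SurfaceMesh,
    truth: GroundTruth,
    config: ScenarioConfig,
    sites: Optional[np.ndarray] = None,
) -> tuple:
    """Per-site bipole sets whose signal content encodes the activation field.

    Each site's electrogram is a sum of sharp biphasic (Gaussian-derivative)
    wavelets: one primary wavelet whose slope-threshold offset equals the LAT
    of the nearest conducting vertex, low-amplitude earlier wavelets when the
    local activation spread is large (fractionation in slow zones), and a
    far-side component when the sensed activation times split into clusters
    separated by an isoelectric gap (split potentials along lines of block).
    Sites over non-conducting regions see only an attenuated far-field
    component (peak-to-peak below the 1.5 mV abnormal-voltage threshold).

    Returns ``(bipole_sets, site_truth)`` where ``site_truth`` is a record
    array with per-site true LAT and region label.
    """
    ecfg = config.egm
    if ecfg.rate_hz < 1000:
        raise ValueError("electrogram rate must be >= 1000 Hz "
                         "(annotation resolution contract)")
    if sites is None:
        sites = sample_sites(config, mesh)
    sites = np.asarray(sites, dtype=float)
    if sites.shape[1] == 2:
        sites = np.column_stack([sites, np.zeros(len(sites))])

    rng = substream(config.seed, "egm")
    cond_idx = np.flatnonzero(mesh.conducting & np.isfinite(truth.lat_ms))
    tree = cKDTree(mesh.vertices[cond_idx])
    all_tree = cKDTree(mesh.vertices)

    # distance to nearest non-conducting vertex (border-zone attenuation)
    noncond = np.flatnonzero(~mesh.conducting)
    nc_tree = cKDTree(mesh.vertices[noncond]) if len(noncond) else None

    sigma = ecfg.wavelet_sigma_ms
    dt = 1000.0 / ecfg.rate_hz
    bipole_sets = []
    site_truth = np.zeros(
        len(sites),
        dtype=[("lat_ms", float), ("label", np.int64), ("on_conducting", bool)],
    )

    for si, pos in enumerate(sites):
        neigh = tree.query_ball_point(pos, ecfg.sensing_radius_mm)
        nearest_any = int(all_tree.query(pos)[1])
        label = int(mesh.vertex_label[nearest_any])
        on_cond = label == 0

        if len(neigh) == 0:
            # nothing sensed: noise-only trace
            t0 = 0.0
            n_samp = int(round(60.0 / dt)) + 1
            clean = np.zeros(n_samp)
            local_lat = np.nan
        else:
            sensed = np.sort(truth.lat_ms[cond_idx[neigh]])
            d_near, i_near = tree.query(pos)
            local_lat = float(truth.lat_ms[cond_idx[i_near]])
            sensed = sensed[sensed <= local_lat + 1e-9]

            # cluster the sensed activation times; gaps beyond the split
            # threshold become distinct components
            comps = [local_lat]
            clusters = _cluster(sensed, ecfg.split_gap_ms)
            local_cluster = clusters[-1]
            amp_comp = [1.0]
            for cl in clusters[:-1]:
                comps.append(float(cl.max()))
                amp_comp.append(rng.uniform(0.25, 0.6))
            # fractionated extras inside the local cluster, spaced widely
            # enough (7.5 ms) to resolve as distinct deflections
            span = local_lat - float(local_cluster.min())
            if span >= ecfg.fractionation_spread_ms:
                k = min(4, int((min(span, 45.0) - 6.0) / 7.5))
                for j in range(1, k + 1):
                    comps.append(local_lat - 6.0 - 7.5 * j)
                    amp_comp.append(rng.uniform(0.1, 0.35))

            # base amplitude by region
            if on_cond:
                base = rng.uniform(*ecfg.normal_p2p_mV)
                if nc_tree is not None:
                    d_nc = nc_tree.query(pos)[0]
                    if d_nc <= ecfg.border_zone_mm:
                        base *= rng.uniform(*ecfg.border_attenuation)
            else:
                base = rng.uniform(*ecfg.farfield_p2p_mV)

            t_start = min(comps) - 12.0
            t_end = local_lat + 12.0
            n_samp = int(np.ceil((t_end - t_start) / dt)) + 1
            t0 = t_start
            t_grid = t0 + np.arange(n_samp) * dt
            clean = np.zeros(n_samp)
            for tc, rel_amp in zip(comps, amp_comp):
                p2p = base * rel_amp
                A = p2p / (2.0 * np.exp(-0.5))
                center = tc - _offset_shift(A, sigma)
                u = (t_grid - center) / sigma
                clean += -A * u * np.exp(-0.5 * u * u)

        # orthogonal bipole pairs: the best-aligned bipole keeps the full
        # amplitude, the others are attenuated by orientation
        gains = np.ones(ecfg.n_bipoles)
        gains[1:] = rng.uniform(0.3, 0.95, size=ecfg.n_bipoles - 1)
        rng.shuffle(gains)
        orientations = ["along" if k % 2 == 0 else "across"
                        for k in range(ecfg.n_bipoles)]
        bipoles = []
        for k in range(ecfg.n_bipoles):
            noise = (
                rng.normal(0.0, ecfg.noise_mV, size=len(clean))
                if ecfg.noise_mV > 0
                else 0.0
            )
            bipoles.append(
                Electrogram(
                    samples=gains[k] * clean + noise,
                    rate_hz=ecfg.rate_hz,
                    t0_ms=t0,
                    orientation=orientations[k],
                )
            )
        bipole_sets.append(
            BipoleSet(site_position=pos.copy(), bipoles=bipoles, spacing_mm=3.0)
        )
        site_truth[si] = (local_lat, label, on_cond)

    return bipole_sets, site_truth


def _cluster(sorted_times: np.ndarray, gap_ms: float) -> list:
    """Split sorted times into clusters separated by more than gap_ms."""
    if len(sorted_times) == 0:
        return [np.array([np.nan])]
    cuts = np.flatnonzero(np.diff(sorted_times) > gap_ms)
    return np.split(sorted_times, cuts + 1)


def _offset_shift(amplitude: float, sigma: float, min_slope: float = 0.1) -> float:
    """Time from wavelet centre to where |slope| last exceeds ``min_slope``.

    The primary wavelet is centred so that this point lands exactly on the
    true LAT; the annotation default slope threshold (0.1 mV/ms) is part of
    the signal-model contract.
    """
    u = np.linspace(0.0, 6.0, 2001)
    slope = amplitude / sigma * np.abs((u * u - 1.0) * np.exp(-0.5 * u * u))
    above = np.flatnonzero(slope >= min_slope)
    if len(above) == 0:
        return 0.0
    return float(u[above[-1]] * sigma)
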