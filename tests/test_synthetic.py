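"""Synthetic study generator: surfaces, activation, electrograms, ablation."""
import warnings

import networkx as nx
import numpy as np
import pytest

import ilamap as il
from ilamap.config import LABEL_CODES
from ilamap.egm import AnnotationConfig, annotate_last_deflection
from ilamap.mesh import SurfaceMesh, build_graph_edges, grid_mesh
from ilamap.synthetic import build_cv_field


# ------------------------------------------------------------------ surface
def test_no_extra_structures_means_only_annuli_labels():
    cfg = il.ScenarioConfig(
        geometry=il.GeometryConfig("sheet", (40.0, 30.0), 1.0),
        structures=[
            il.StructureSpec("tricuspid_annulus", (0.0, 0.0, 40.0, 4.0)),
            il.StructureSpec("pulmonary_annulus", (0.0, 26.0, 40.0, 30.0)),
        ],
        pacing_sources=[((1.0, 15.0), 0.0)],
    )
    mesh = il.generate_surface(cfg)
    present = set(np.unique(mesh.vertex_label))
    assert present == {
        0,
        LABEL_CODES["tricuspid_annulus"],
        LABEL_CODES["pulmonary_annulus"],
    }


def test_requested_corridor_width_within_10pct_vs_bruteforce():
    cfg = il.corridor_scenario(0.3, width_mm=11.0, seed=2)
    mesh = il.generate_surface(cfg)
    # independent oracle: all-pairs distance between the two boundaries
    la, lb = il.AI_BOUNDS["AI3"]
    pa = mesh.vertices[mesh.boundary_of(la)]
    pb = mesh.vertices[mesh.boundary_of(lb)]
    best = min(
        float(np.linalg.norm(p - q)) for p in pa for q in pb
    )
    assert 9.9 <= best <= 12.1
    assert np.isclose(il.measure_corridor_width(mesh, "AI3"), best)


def test_destroyed_corridor_raises_naming_it():
    cfg = il.corridor_scenario(0.3, width_mm=12.0, seed=0)
    # shrink the gap to 5 mm without updating the corridor request
    cfg.structures[0].rect = (59.0, 27.5, 77.0, 50.0)
    cfg.structures[1].rect = (59.0, 0.0, 77.0, 22.5)
    with pytest.raises(ValueError, match="AI3"):
        il.generate_surface(cfg)


# --------------------------------------------------------------- activation
def test_strip_distance_speed_identity():
    mesh = grid_mesh((50.0, 6.0), 1.0)
    build_graph_edges(mesh)
    lat = il.simulate_activation(mesh, np.ones(mesh.n_vertices), [((0.0, 3.0), 0.0)])
    distal = np.flatnonzero(
        (mesh.vertices[:, 0] == 50.0) & (mesh.vertices[:, 1] == 3.0)
    )[0]
    assert lat[distal] == pytest.approx(50.0, rel=0.03)


def test_fig1b_corridor_18mm_at_1p3_takes_14ms():
    """18 mm isthmus at 1.3 m/s: conduction time ~14 ms."""
    cfg = il.corridor_scenario(planted_cv=1.3, seed=4)
    mesh = il.generate_surface(cfg)
    truth = il.ground_truth(cfg, mesh)
    ai = il.delineate_isthmuses(mesh)[0]
    entry_v = int(np.argmin(np.linalg.norm(mesh.vertices - ai.entry, axis=1)))
    exit_v = int(np.argmin(np.linalg.norm(mesh.vertices - ai.exit, axis=1)))
    ct = abs(truth.lat_ms[exit_v] - truth.lat_ms[entry_v])
    assert ct == pytest.approx(14.0, abs=1.5)
    assert il.report_cv(il.conduction_velocity(18.0, ct)) == pytest.approx(
        1.3, abs=0.1
    )


def test_small_graph_lat_equals_exhaustive_path_enumeration():
    """First-arrival on an arbitrary 10-vertex graph vs brute force."""
    rng = np.random.default_rng(7)
    pos = rng.uniform(0, 10, size=(10, 3))
    pos[:, 2] = 0.0
    tris = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4], [3, 4, 5],
                     [4, 5, 6], [5, 6, 7], [6, 7, 8], [7, 8, 9]])
    mesh = SurfaceMesh(pos, tris, np.zeros(10, dtype=int))
    cv = rng.uniform(0.2, 2.0, size=10)
    lat = il.simulate_activation(mesh, cv, [(0, 0.0)])

    # oracle: enumerate every simple path, applying the same edge-time rule
    g = nx.Graph()
    for a, b in mesh.graph_edges:
        length = float(np.linalg.norm(pos[a] - pos[b]))
        g.add_edge(int(a), int(b),
                   w=length * 0.5 * (1.0 / cv[a] + 1.0 / cv[b]))
    for target in range(10):
        best = min(
            sum(g[u][v]["w"] for u, v in zip(p[:-1], p[1:]))
            for p in nx.all_simple_paths(g, 0, target)
        ) if target != 0 else 0.0
        assert lat[target] == pytest.approx(best, abs=1e-9)


def test_source_on_nonconducting_vertex_raises():
    cfg = il.corridor_scenario(0.3, seed=0)
    mesh = il.generate_surface(cfg)
    bad = int(mesh.label_vertices("vsd_patch")[0])
    with pytest.raises(ValueError, match="non-conducting"):
        il.simulate_activation(mesh, build_cv_field(cfg, mesh), [(bad, 0.0)])


# ------------------------------------------------------------- electrograms
def test_egm_rate_below_1000hz_rejected():
    cfg = il.corridor_scenario(0.3, seed=0)
    cfg.egm.rate_hz = 500.0
    with pytest.raises(ValueError, match="1000"):
        il.generate_surface(cfg)


def test_noiseless_offset_encodes_true_lat(slow_corridor_result):
    res = slow_corridor_result
    pts = res.points
    on_cond = res.site_truth["on_conducting"][pts["site_id"].to_numpy()]
    used = pts[pts["used"] & on_cond & np.isfinite(pts["true_lat_ms"])]
    err = np.abs(used["lat_ms"] - used["true_lat_ms"])
    one_sample = 1000.0 / res.config.egm.rate_hz
    assert len(used) > 100
    assert err.max() <= one_sample + 1e-9


def test_scar_sites_read_below_1p5mV(default_map_result):
    res = default_map_result
    scar = LABEL_CODES["scar_patch"]
    labels = res.site_truth["label"][res.points["site_id"].to_numpy()]
    scar_pts = res.points[(labels == scar) & res.points["used"]]
    assert len(scar_pts) > 3
    assert (scar_pts["voltage_mV"] < 1.5).all()


def test_deterministic_electrograms_under_fixed_seed():
    cfg = il.corridor_scenario(0.4, seed=12)
    out = []
    for _ in range(2):
        mesh = il.generate_surface(cfg)
        truth = il.ground_truth(cfg, mesh)
        bs, st = il.synthesize_electrograms(mesh, truth, cfg)
        out.append((bs, st))
    (bs1, st1), (bs2, st2) = out
    assert np.array_equal(st1["lat_ms"], st2["lat_ms"], equal_nan=True)
    for b1, b2 in zip(bs1[::50], bs2[::50]):
        for e1, e2 in zip(b1.bipoles, b2.bipoles):
            assert np.array_equal(e1.samples, e2.samples)


# ----------------------------------------------------------------- ablation
def test_empty_polyline_is_identity():
    mesh = il.generate_surface(il.ablation_demo_scenario())
    out = il.apply_ablation_line(mesh, [])
    assert np.array_equal(out.graph_edges, mesh.graph_edges)


def test_polyline_inside_nonconducting_region_warns_noop():
    mesh = il.generate_surface(il.ablation_demo_scenario())
    with pytest.warns(UserWarning, match="no conducting edge"):
        out = il.apply_ablation_line(mesh, [(30.5, 1.0), (40.5, 1.0)])
    assert np.array_equal(out.graph_edges, mesh.graph_edges)


def test_transection_without_detour_unmaps_distal():
    cfg = il.ablation_demo_scenario(detour=False)
    mesh = il.generate_surface(cfg)
    cut = il.apply_ablation_line(mesh, [(35.5, 13.0), (35.5, 27.0)])
    # graph-connectivity oracle: the distal corridor half is disconnected
    from scipy.sparse.csgraph import connected_components

    n, comp = connected_components(cut.length_graph())
    xy = cut.vertices
    distal = cut.conducting & (xy[:, 0] > 36) & (xy[:, 0] < 49) \
        & (xy[:, 1] > 15) & (xy[:, 1] < 25)
    src = int(np.argmin(np.linalg.norm(xy - np.array([1.0, 20.0, 0.0]), axis=1)))
    assert (comp[distal] != comp[src]).all()
    with pytest.warns(UserWarning, match="unreachable"):
        lat = il.simulate_activation(cut, build_cv_field(cfg, cut),
                                     cfg.pacing_sources)
    assert np.isnan(lat[distal]).all()
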