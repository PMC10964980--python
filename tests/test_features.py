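"""Deceleration zones, crowding counts, block lines, collisions."""
import numpy as np
import pandas as pd
import pytest

import ilamap as il
from ilamap.features import (
    DecelerationZone,
    FeatureThresholds,
    count_isochrones_in_radius,
    detect_block_lines,
    detect_collisions,
    detect_deceleration_zones,
    flag_extreme_slowing,
)
from ilamap.ilam import ActivationMap, IsochronalMap, build_ilam
from ilamap.mesh import build_graph_edges, grid_mesh
from scipy.sparse.csgraph import dijkstra


def _mesh(size=(30.0, 10.0)):
    m = grid_mesh(size, 1.0)
    build_graph_edges(m)
    return m


def _im_with_index(mesh, iso_index, lat=None):
    idx = np.asarray(iso_index, dtype=np.int64)
    if lat is None:
        lat = idx * 10.0
    edges = np.linspace(0.0, float(np.nanmax(lat)) or 1.0, 9)
    return IsochronalMap(mesh, np.asarray(lat, float), edges, idx,
                         max(float(np.nanmax(lat)), 1.0))


def test_count_one_when_isochrone_much_wider_than_radius():
    mesh = _mesh()
    im = _im_with_index(mesh, np.zeros(mesh.n_vertices, dtype=int))
    assert count_isochrones_in_radius(im, mesh.n_vertices // 2, 10.0) == 1


def test_count_matches_bruteforce_dijkstra_oracle():
    mesh = _mesh((16.0, 8.0))
    rng = np.random.default_rng(5)
    idx = rng.integers(0, 8, size=mesh.n_vertices)
    im = _im_with_index(mesh, idx)
    dist = dijkstra(mesh.length_graph())  # exhaustive all-pairs oracle
    for v in range(0, mesh.n_vertices, 7):
        inside = dist[v] <= 10.0
        want = len(np.unique(idx[inside]))
        assert count_isochrones_in_radius(im, v, 10.0) == want


def test_unmapped_vertex_raises():
    mesh = _mesh((10.0, 5.0))
    idx = np.zeros(mesh.n_vertices, dtype=int)
    idx[3] = -1
    lat = np.zeros(mesh.n_vertices)
    lat[3] = np.nan
    im = _im_with_index(mesh, idx, lat)
    with pytest.raises(ValueError, match="not mapped"):
        count_isochrones_in_radius(im, 3)


def test_exactly_three_isochrones_in_radius_is_no_dz():
    """Strict '>3': 10 mm-wide isochrones give counts of exactly 3."""
    mesh = _mesh((30.0, 12.0))
    x = mesh.vertices[:, 0]
    im = _im_with_index(mesh, np.clip(x // 10, 0, 7).astype(int), lat=x)
    counts = [count_isochrones_in_radius(im, v, 10.0)
              for v in range(0, mesh.n_vertices, 11)]
    assert max(counts) == 3
    assert detect_deceleration_zones(im) == []


def test_narrow_isochrones_do_trigger_dz():
    mesh = _mesh((30.0, 12.0))
    x = mesh.vertices[:, 0]
    im = _im_with_index(mesh, np.clip(x // 4, 0, 7).astype(int), lat=x)
    zones = detect_deceleration_zones(im)
    assert len(zones) >= 1
    assert all(z.area_mm2 >= 10.0 for z in zones)


def test_fast_uniform_map_has_no_dz(fast_corridor_result):
    assert len(fast_corridor_result.zones) == 0


def test_slow_corridor_yields_single_dz_overlapping_it(slow_corridor_result):
    res = slow_corridor_result
    assert len(res.zones) == 1
    ai = res.isthmuses[0]
    overlap = set(map(int, res.zones[0].member_vertices)) & set(
        map(int, ai.member_vertices)
    )
    assert overlap
    assert ai.dz


def test_dz_monotone_in_cv(slow_corridor_result):
    """Lowering the planted CV never removes the corridor DZ."""
    res_slower = il.analyze_scenario(
        il.corridor_scenario(planted_cv=0.1, seed=3), detect_extras=False
    )
    assert slow_corridor_result.isthmuses[0].dz
    assert res_slower.isthmuses[0].dz


# ---------------------------------------------------------- extreme slowing
def _zone(peak):
    return DecelerationZone(np.array([0, 1, 2]), peak, np.zeros(3), 12.0)


def _pts(fractionated):
    return pd.DataFrame({
        "x": 0.0, "y": 0.0, "z": 0.0, "vertex": [0, 1, 2],
        "used": True, "fractionated": fractionated,
        "split": False, "gap_ms": 0.0, "lat_ms": 1.0,
    })


def test_extreme_requires_both_crowding_and_fractionation():
    assert flag_extreme_slowing(_zone(7), _pts([True, True, False]))
    assert not flag_extreme_slowing(_zone(4), _pts([False, False, False]))
    assert not flag_extreme_slowing(_zone(7), _pts([False, False, False]))


# --------------------------------------------------------------- block lines
def test_smooth_single_wavefront_map_has_no_block_lines(fast_corridor_result):
    res = fast_corridor_result
    assert detect_block_lines(res.ilam, res.amap.points) == []


def test_subthreshold_jump_without_splits_is_not_a_block_line():
    mesh = _mesh((20.0, 8.0))
    x = mesh.vertices[:, 0]
    lat = np.where(x < 10, x, x + 5.0)  # 0.5-bin jump at x=10
    im = build_ilam(ActivationMap(mesh, None, vertex_lat=lat * 8.0 / 2.0))
    pts = pd.DataFrame({
        "x": [10.0], "y": [4.0], "z": [0.0], "lat_ms": [40.0],
        "split": [False], "gap_ms": [0.0], "used": [True],
    })
    assert detect_block_lines(im, pts) == []


# ---------------------------------------------------------------- collisions
def _strip_lat(sources):
    strip = il.ScenarioConfig(
        geometry=il.GeometryConfig("sheet", (50.0, 10.0), 1.0),
        pacing_sources=sources,
    )
    mesh = il.generate_surface(strip)
    lat = il.simulate_activation(mesh, np.full(mesh.n_vertices, 1.0), sources)
    return mesh, build_ilam(ActivationMap(mesh, None, vertex_lat=lat))


def test_strip_paced_from_both_ends_collides_at_midline():
    mesh, im = _strip_lat([((0.0, 5.0), 0.0), ((50.0, 5.0), 0.0)])
    colls = detect_collisions(im)
    assert colls
    xs = mesh.vertices[np.concatenate(colls), 0]
    assert np.allclose(xs, 25.0)


def test_single_source_map_has_no_collisions():
    _, im = _strip_lat([((0.0, 5.0), 0.0)])
    assert detect_collisions(im) == []


def test_offset_sources_shift_locus_toward_later_source():
    """Locus from first-arrival oracle: min(x, 20 + (50-x)) maximal at x=35."""
    mesh, im = _strip_lat([((0.0, 5.0), 0.0), ((50.0, 5.0), 20.0)])
    colls = detect_collisions(im)
    xs = mesh.vertices[np.concatenate(colls), 0]
    # brute-force two-source arrival on the centre row
    x = np.arange(51.0)
    oracle = np.minimum(x, 20.0 + (50.0 - x))
    assert np.allclose(xs, x[np.argmax(oracle)])
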