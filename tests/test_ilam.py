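"""Point projection, LAT interpolation, and the 8-isochrone partition."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ilamap as il
from ilamap.ilam import (
    ActivationMap,
    build_ilam,
    interpolate_lat,
    project_points,
    used_point_rate,
)
from ilamap.mesh import build_graph_edges, grid_mesh


def _mesh(size=(20.0, 10.0)):
    m = grid_mesh(size, 1.0)
    build_graph_edges(m)
    return m


def _points(rows):
    df = pd.DataFrame(rows)
    for col, default in [("voltage_mV", 2.0), ("split", False), ("gap_ms", 0.0),
                         ("n_deflections", 1), ("fractionated", False),
                         ("used", True), ("z", 0.0)]:
        if col not in df:
            df[col] = default
    df["site_id"] = np.arange(len(df))
    return df


# -------------------------------------------------------------- projection
def test_point_on_vertex_projects_to_it():
    mesh = _mesh()
    amap = project_points(ActivationMap(mesh, _points([{"x": 3.0, "y": 4.0, "lat_ms": 10.0}])))
    v = int(amap.points["vertex"].iloc[0])
    assert np.allclose(mesh.vertices[v], [3.0, 4.0, 0.0])


def test_far_point_is_rejected():
    mesh = _mesh()
    amap = project_points(
        ActivationMap(mesh, _points([{"x": 10.0, "y": 5.0, "z": 0.0, "lat_ms": 1.0},
                                     {"x": 10.0, "y": 5.0, "z": 10.0, "lat_ms": 2.0}])),
        max_distance_mm=5.0,
    )
    assert bool(amap.points["used"].iloc[0])
    assert not bool(amap.points["used"].iloc[1])


def test_random_cloud_matches_bruteforce_nearest_vertex():
    mesh = _mesh()
    rng = np.random.default_rng(3)
    pts = _points([
        {"x": x, "y": y, "lat_ms": t}
        for (x, y), t in zip(rng.uniform(0, [20, 10], size=(40, 2)),
                             rng.uniform(0, 100, 40))
    ])
    amap = project_points(ActivationMap(mesh, pts))
    for _, row in amap.points.iterrows():
        d = np.linalg.norm(mesh.vertices - [row.x, row.y, row.z], axis=1)
        assert int(row.vertex) == int(np.argmin(d))


# ------------------------------------------------------------ interpolation
def test_single_point_gives_constant_field_within_radius():
    mesh = _mesh((6.0, 4.0))
    amap = project_points(ActivationMap(mesh, _points([{"x": 3.0, "y": 2.0, "lat_ms": 42.0}])))
    amap = interpolate_lat(amap, fill_radius_mm=50.0)
    assert np.allclose(amap.vertex_lat, 42.0)


def test_two_points_average_at_equidistant_vertex():
    mesh = _mesh()
    amap = project_points(ActivationMap(mesh, _points([
        {"x": 6.0, "y": 5.0, "lat_ms": 0.0},
        {"x": 14.0, "y": 5.0, "lat_ms": 100.0},
    ])))
    amap = interpolate_lat(amap, fill_radius_mm=50.0)
    mid = int(np.flatnonzero((mesh.vertices[:, 0] == 10.0)
                             & (mesh.vertices[:, 1] == 5.0))[0])
    assert amap.vertex_lat[mid] == pytest.approx(50.0)
    # exact at the point-bearing vertices
    for x, want in [(6.0, 0.0), (14.0, 100.0)]:
        v = int(np.flatnonzero((mesh.vertices[:, 0] == x)
                               & (mesh.vertices[:, 1] == 5.0))[0])
        assert amap.vertex_lat[v] == pytest.approx(want, abs=1e-12)


def test_idw_matches_direct_sum_oracle():
    mesh = _mesh()
    rng = np.random.default_rng(11)
    xy = rng.uniform(0, [20, 10], size=(12, 2))
    lat = rng.uniform(0, 150, 12)
    amap = project_points(ActivationMap(mesh, _points(
        [{"x": x, "y": y, "lat_ms": t} for (x, y), t in zip(xy, lat)]
    )))
    radius = 6.0
    out = interpolate_lat(amap, fill_radius_mm=radius)
    src = amap.points["vertex"].to_numpy()
    uniq = np.unique(src)
    vals = np.array([lat[src == u].mean() for u in uniq])
    d = mesh.geodesic_distances(uniq, limit=radius)
    for v in range(mesh.n_vertices):
        dv = d[:, v]
        if v in uniq:
            want = vals[list(uniq).index(v)]
        elif np.isfinite(dv).any():
            w = np.where(np.isfinite(dv), 1.0 / np.maximum(dv, 1e-12) ** 2, 0.0)
            want = np.sum(w * vals) / w.sum()
        else:
            assert np.isnan(out.vertex_lat[v])
            continue
        assert out.vertex_lat[v] == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------- isochrones
def _ilam_from_lat(mesh, lat):
    return build_ilam(ActivationMap(mesh, None, vertex_lat=np.asarray(lat, float)))


def test_eight_equal_bins_and_example_index():
    mesh = _mesh((4.0, 2.0))
    lat = np.linspace(0.0, 160.0, mesh.n_vertices)
    lat[5] = 95.0
    im = _ilam_from_lat(mesh, lat)
    assert len(im.bin_edges) == 9
    assert np.allclose(np.diff(im.bin_edges), 20.0)
    assert im.iso_index[5] == 4
    assert im.iso_index[np.argmax(lat)] == 7  # last bin right-closed
    assert im.total_activation_time == pytest.approx(160.0)


def test_total_activation_time_151ms():
    mesh = _mesh((4.0, 2.0))
    lat = np.linspace(0.0, 151.0, mesh.n_vertices)
    im = _ilam_from_lat(mesh, lat)
    assert im.total_activation_time == pytest.approx(151.0)


def test_degenerate_range_raises():
    mesh = _mesh((4.0, 2.0))
    with pytest.raises(ValueError, match="degenerate"):
        _ilam_from_lat(mesh, np.full(mesh.n_vertices, 7.0))


@given(arrays(float, 40, elements=st.floats(0, 500)))
@settings(max_examples=40, deadline=None)
def test_partition_properties(lat):
    mesh = _mesh((7.0, 4.0))
    if np.ptp(lat) == 0:
        return
    im = _ilam_from_lat(mesh, lat)
    width = im.total_activation_time / 8
    assert np.allclose(np.diff(im.bin_edges), width, rtol=1e-9)
    idx = im.iso_index[im.mapped]
    assert ((idx >= 0) & (idx <= 7)).all()
    # every mapped LAT lies inside its bin (last bin right-closed)
    lo = im.bin_edges[idx]
    hi = im.bin_edges[idx + 1]
    lats = im.vertex_lat[im.mapped]
    assert ((lats >= lo - 1e-9) & (lats <= hi + 1e-9)).all()
    # re-running is bit-identical
    im2 = _ilam_from_lat(mesh, lat)
    assert np.array_equal(im.iso_index, im2.iso_index)
    assert np.array_equal(im.bin_edges, im2.bin_edges)


def test_used_point_rate_to_one_decimal():
    assert used_point_rate(2149, 19060) == 11.3
    with pytest.raises(ValueError):
        used_point_rate(1, 0)
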