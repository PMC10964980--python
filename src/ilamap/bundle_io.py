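"""Map-bundle file formats.

A bundle is a directory with a JSON manifest (format version, seed, rhythm,
per-file SHA-256 checksums), the mesh as legacy-ASCII VTK (with per-vertex
labels and, when available, true LATs as point-data arrays) and PLY, the
mapping points/annotations as CSV, the electrogram store as CSV, and the
ground truth as JSON.  Reads verify checksums and fail naming the file.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

from .egm import BipoleSet, Electrogram
from .mesh import SurfaceMesh, build_graph_edges
from .synthetic import GroundTruth

FORMAT_VERSION = "1.0"


# --------------------------------------------------------------------------
# legacy-ASCII VTK polydata
# --------------------------------------------------------------------------
def write_vtk(path, mesh: SurfaceMesh, point_data: Optional[dict] = None) -> None:
    """Write the mesh as VTK legacy ASCII polydata with point-data arrays."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "ilamap surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{v:.17g}" for v in row) for row in mesh.vertices]
    m = len(mesh.triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    data = {"label": mesh.vertex_label, **(point_data or {})}
    lines.append(f"POINT_DATA {mesh.n_vertices}")
    for name, arr in data.items():
        arr = np.asarray(arr)
        dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {dtype} 1")
        lines.append("LOOKUP_TABLE default")
        if dtype == "int":
            lines += [str(int(v)) for v in arr]
        else:
            lines += [f"{float(v):.17g}" for v in arr]
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> tuple:
    """Read legacy-ASCII VTK polydata back: (vertices, triangles, point_data)."""
    tokens = Path(path).read_text().split("\n")
    i = 0
    verts = tris = None
    point_data = {}
    n_points = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n_points = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n_points:
                vals += [float(t) for t in tokens[i].split()]
                i += 1
            verts = np.array(vals).reshape(n_points, 3)
            continue
        if line.startswith("POLYGONS"):
            m = int(line.split()[1])
            rows = []
            i += 1
            for _ in range(m):
                parts = [int(t) for t in tokens[i].split()]
                rows.append(parts[1 : 1 + parts[0]])
                i += 1
            tris = np.array(rows)
            continue
        if line.startswith("SCALARS"):
            _, name, dtype = line.split()[:3]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n_points:
                vals += tokens[i].split()
                i += 1
            conv = int if dtype == "int" else float
            point_data[name] = np.array([conv(v) for v in vals])
            continue
        i += 1
    return verts, tris, point_data


def write_ply(path, mesh: SurfaceMesh) -> None:
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    Path(path).write_bytes(tm.export(file_type="ply", encoding="ascii"))


# --------------------------------------------------------------------------
# electrogram store
# --------------------------------------------------------------------------
def write_egms(path, bipole_sets: list) -> None:
    rows = []
    for si, bs in enumerate(bipole_sets):
        for bi, b in enumerate(bs.bipoles):
            rows.append(
                {
                    "site_id": si,
                    "bipole_id": bi,
                    "orientation": b.orientation,
                    "x": bs.site_position[0],
                    "y": bs.site_position[1],
                    "z": bs.site_position[2],
                    "spacing_mm": bs.spacing_mm,
                    "t0_ms": b.t0_ms,
                    "rate_hz": b.rate_hz,
                    "samples": " ".join(f"{v:.17g}" for v in b.samples),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_egms(path) -> list:
    df = pd.read_csv(path)
    out = []
    for site_id, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("bipole_id")
        first = grp.iloc[0]
        bipoles = [
            Electrogram(
                samples=np.array([float(t) for t in str(r.samples).split()]),
                rate_hz=float(r.rate_hz),
                t0_ms=float(r.t0_ms),
                orientation=str(r.orientation),
            )
            for r in grp.itertuples()
        ]
        out.append(
            BipoleSet(
                site_position=np.array([first.x, first.y, first.z]),
                bipoles=bipoles,
                spacing_mm=float(first.spacing_mm),
            )
        )
    return out


# --------------------------------------------------------------------------
# bundle
# --------------------------------------------------------------------------
@dataclass
class MapBundle:
    manifest: dict
    mesh: SurfaceMesh
    points: Optional[pd.DataFrame] = None
    bipole_sets: Optional[list] = None
    ground_truth: Optional[GroundTruth] = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(
    bundle_dir,
    mesh: SurfaceMesh,
    points: Optional[pd.DataFrame] = None,
    bipole_sets: Optional[list] = None,
    ground_truth: Optional[GroundTruth] = None,
    seed: int = 0,
    rhythm: str = "paced",
    extra_manifest: Optional[dict] = None,
) -> Path:
    """Write a bundle directory; returns its path."""
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)

    point_data = {}
    if ground_truth is not None:
        point_data["lat_true_ms"] = np.nan_to_num(ground_truth.lat_ms, nan=-1.0)
        point_data["cv_true"] = np.nan_to_num(ground_truth.cv_field, nan=-1.0)
    files = {}
    write_vtk(bundle_dir / "mesh.vtk", mesh, point_data)
    files["mesh_vtk"] = "mesh.vtk"
    write_ply(bundle_dir / "mesh.ply", mesh)
    files["mesh_ply"] = "mesh.ply"
    np.savetxt(
        bundle_dir / "graph_edges.csv",
        mesh.graph_edges,
        fmt="%d",
        delimiter=",",
        header="i,j",
        comments="",
    )
    files["graph_edges"] = "graph_edges.csv"

    if points is not None:
        points.to_csv(bundle_dir / "annotations.csv", index=False)
        files["annotations"] = "annotations.csv"
    if bipole_sets is not None:
        write_egms(bundle_dir / "egms.csv", bipole_sets)
        files["egms"] = "egms.csv"
    if ground_truth is not None:
        gt = {
            "lat_ms": [None if not np.isfinite(v) else float(v)
                       for v in ground_truth.lat_ms],
            "cv_field": [None if not np.isfinite(v) else float(v)
                         for v in ground_truth.cv_field],
            "corridors": ground_truth.corridors,
            "block_vertices": [int(v) for v in ground_truth.block_vertices],
        }
        (bundle_dir / "ground_truth.json").write_text(json.dumps(gt))
        files["ground_truth"] = "ground_truth.json"

    manifest = {
        "format_version": FORMAT_VERSION,
        "seed": int(seed),
        "rhythm": rhythm,
        "mesh_meta": {
            k: v for k, v in mesh.meta.items() if k != "unrolled_xy"
        },
        "files": files,
        "checksums": {
            name: _sha256(bundle_dir / fname) for name, fname in files.items()
        },
        **(extra_manifest or {}),
    }
    (bundle_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle_dir


def read_bundle(bundle_dir) -> MapBundle:
    """Read a bundle back, verifying checksums and the format version."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unknown bundle format version {manifest.get('format_version')!r}"
        )
    for name, fname in manifest["files"].items():
        want = manifest["checksums"][name]
        got = _sha256(bundle_dir / fname)
        if got != want:
            raise ValueError(f"checksum mismatch for {fname}")

    verts, tris, point_data = read_vtk(bundle_dir / manifest["files"]["mesh_vtk"])
    edges = np.loadtxt(
        bundle_dir / manifest["files"]["graph_edges"],
        dtype=np.int64, delimiter=",", skiprows=1,
    ).reshape(-1, 2)
    meta = dict(manifest.get("mesh_meta", {}))
    if "size_mm" in meta:
        meta["size_mm"] = tuple(meta["size_mm"])
    mesh = SurfaceMesh(verts, tris, point_data["label"], edges, meta)
    if meta.get("kind") == "sheet":
        mesh.meta["unrolled_xy"] = mesh.vertices[:, :2].copy()

    points = None
    if "annotations" in manifest["files"]:
        points = pd.read_csv(bundle_dir / manifest["files"]["annotations"])
    bipole_sets = None
    if "egms" in manifest["files"]:
        bipole_sets = read_egms(bundle_dir / manifest["files"]["egms"])
    truth = None
    if "ground_truth" in manifest["files"]:
        gt = json.loads((bundle_dir / manifest["files"]["ground_truth"]).read_text())
        truth = GroundTruth(
            lat_ms=np.array([np.nan if v is None else v for v in gt["lat_ms"]]),
            cv_field=np.array([np.nan if v is None else v for v in gt["cv_field"]]),
            corridors=gt["corridors"],
            block_vertices=np.array(gt["block_vertices"], dtype=np.int64),
        )
    else:
        warnings.warn("bundle has no ground truth; validation stages will "
                      "report 'no truth available'", stacklevel=2)
    return MapBundle(manifest, mesh, points, bipole_sets, truth)
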