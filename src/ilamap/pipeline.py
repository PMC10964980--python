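"""Pipeline drivers: simulate -> annotate -> map -> detect -> analyze -> validate.

`analyze_scenario` runs one synthetic study end to end in memory and is the
workhorse behind the analysis scripts, the staged CLI, and the validation
cohorts.  `corridor_cohort` runs many single-corridor studies with planted
conduction velocities and collects the per-corridor recovery table used for
the DZ-vs-SC-AI validation statistics.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bundle_io
from .config import ScenarioConfig, substream
from .egm import AnnotationConfig, annotate_site, select_best_bipole
from .features import (
    FeatureThresholds,
    detect_block_lines,
    detect_collisions,
    detect_deceleration_zones,
    flag_extreme_slowing,
)
from .ilam import ActivationMap, IsochronalMap, build_ilam, interpolate_lat, project_points
from .isthmus import analyze_isthmus, delineate_isthmuses, isthmus_table
from .mesh import SurfaceMesh
from .stats import validation_report
from .synthetic import (
    GroundTruth,
    generate_surface,
    ground_truth,
    corridor_scenario,
    sample_sites,
    synthesize_electrograms,
)

STAGES = ("simulate", "annotate", "map", "detect", "analyze", "validate")


@dataclass
class MapResult:
    """Everything one synthetic study produces."""

    config: ScenarioConfig
    mesh: SurfaceMesh
    truth: GroundTruth
    bipole_sets: list
    site_truth: np.ndarray
    points: pd.DataFrame
    amap: ActivationMap
    ilam: IsochronalMap
    zones: list
    block_lines: list
    collisions: list
    isthmuses: list
    summary: dict = field(default_factory=dict)


def annotate_bipole_sets(
    bipole_sets: list,
    site_truth: Optional[np.ndarray] = None,
    ann_cfg: Optional[AnnotationConfig] = None,
) -> pd.DataFrame:
    """Best-bipole selection + last-deflection annotation for every site."""
    ann_cfg = ann_cfg or AnnotationConfig()
    rows = []
    for si, bs in enumerate(bipole_sets):
        ann = annotate_site(bs, ann_cfg)
        rows.append(
            {
                "site_id": si,
                "x": bs.site_position[0],
                "y": bs.site_position[1],
                "z": bs.site_position[2],
                "lat_ms": ann.lat_ms,
                "voltage_mV": ann.voltage_mV,
                "split": ann.split,
                "gap_ms": ann.gap_ms,
                "n_deflections": ann.n_deflections,
                "fractionated": ann.n_deflections
                >= ann_cfg.fractionation_min_deflections,
                "used": ann.used,
                "true_lat_ms": (
                    float(site_truth[si]["lat_ms"]) if site_truth is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def analyze_scenario(
    config: ScenarioConfig,
    ann_cfg: Optional[AnnotationConfig] = None,
    thresholds: Optional[FeatureThresholds] = None,
    detect_extras: bool = True,
) -> MapResult:
    """Run one scenario end to end (simulate through isthmus analysis)."""
    thresholds = thresholds or FeatureThresholds()
    mesh = generate_surface(config)
    truth = ground_truth(config, mesh)
    sites = sample_sites(config, mesh)
    bipole_sets, site_truth = synthesize_electrograms(mesh, truth, config, sites)

    points = annotate_bipole_sets(bipole_sets, site_truth, ann_cfg)
    amap = ActivationMap(mesh, points, rhythm=config.rhythm)
    amap = project_points(amap)
    amap = interpolate_lat(amap)
    ilam = build_ilam(amap)

    zones = detect_deceleration_zones(ilam, thresholds)
    for z in zones:
        flag_extreme_slowing(z, amap.points, thresholds)
    block_lines = (
        detect_block_lines(ilam, amap.points, thresholds) if detect_extras else []
    )
    collisions = detect_collisions(ilam) if detect_extras else []

    isthmuses = delineate_isthmuses(mesh)
    for ai in isthmuses:
        try:
            analyze_isthmus(ai, ilam, zones)
        except ValueError as err:
            warnings.warn(f"{ai.ai_type}: {err}", stacklevel=2)

    for z in zones:
        overlapping = [
            ai.ai_type for ai in isthmuses
            if set(map(int, z.member_vertices)) & set(map(int, ai.member_vertices))
        ]
        z.overlapping_ai = overlapping[0] if overlapping else None

    summary = {
        "seed": config.seed,
        "n_acquired": amap.n_acquired,
        "n_used": amap.n_used,
        "used_point_rate_pct": amap.used_point_rate(),
        "total_activation_time_ms": round(ilam.total_activation_time, 1),
        "n_dz": len(zones),
        "n_block_lines": len(block_lines),
        "n_collision_sets": len(collisions),
        "isthmuses": isthmus_table(isthmuses).to_dict(orient="records"),
    }
    return MapResult(
        config, mesh, truth, bipole_sets, site_truth, points, amap, ilam,
        zones, block_lines, collisions, isthmuses, summary,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------
def corridor_cohort(
    n_corridors: int = 28,
    seed: int = 0,
    point_density: float = 20.0,
    noise_mV: float = 0.0,
    cv_range: tuple = (0.1, 1.5),
) -> pd.DataFrame:
    """Single-corridor studies with planted CVs uniform on ``cv_range``.

    Returns the per-corridor recovery table: planted CV and SC flag, the
    estimated conduction time / CV / isochrones-per-cm, and whether a
    deceleration zone overlapped the corridor.
    """
    rng = substream(seed, "cohort")
    cvs = rng.uniform(*cv_range, size=n_corridors)
    ai_cycle = ("AI3", "AI1", "AI2", "AI4")
    rows = []
    for k, cv in enumerate(cvs):
        cfg = corridor_scenario(
            planted_cv=float(cv),
            ai_type=ai_cycle[k % 4],
            seed=int(substream(seed, f"map{k}").integers(2**31 - 1)),
            point_density=point_density,
            noise_mV=noise_mV,
        )
        res = analyze_scenario(cfg, detect_extras=False)
        ai = next(a for a in res.isthmuses if a.ai_type == cfg.corridors[0].ai_type)
        rows.append(
            {
                "corridor": k,
                "ai_type": ai.ai_type,
                "planted_cv": float(cv),
                "sc_true": bool(cv < 0.5),
                "width_mm": ai.width_mm,
                "length_mm": ai.axis_length_mm,
                "conduction_time_ms": ai.conduction_time_ms,
                "cv_est": ai.cv,
                "isochrones_per_cm": ai.isochrones_per_cm,
                "dz": bool(ai.dz),
                "n_dz": len(res.zones),
                "total_activation_time_ms": res.ilam.total_activation_time,
                "used_point_rate_pct": res.amap.used_point_rate(),
            }
        )
    return pd.DataFrame(rows)


def cohort_validation(cohort: pd.DataFrame, seed: int = 0):
    """DZ-presence vs planted SC status validation over a corridor cohort."""
    return validation_report(
        cohort["dz"].to_numpy(),
        cohort["sc_true"].to_numpy(),
        cohort["isochrones_per_cm"].to_numpy(),
        cohort["cv_est"].to_numpy(),
        seed=seed,
    )


# --------------------------------------------------------------------------
# staged, file-based pipeline (the CLI backend)
# --------------------------------------------------------------------------
def _require(path: Path, stage_needed: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}; run '{stage_needed}' first"
        )


def run_pipeline(
    config: ScenarioConfig,
    out_dir,
    stages: Optional[list] = None,
    ann_cfg: Optional[AnnotationConfig] = None,
) -> Path:
    """Execute the requested stages in order, file-to-file under ``out_dir``.

    Each stage reads the previous stage's artifacts; a missing upstream
    artifact raises an error naming the stage to run first.  Every run
    refreshes ``provenance.json`` (config hash, seed, stages executed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)
    bundle_dir = out_dir / "bundle"
    thresholds = FeatureThresholds()

    if "simulate" in stages:
        mesh = generate_surface(config)
        truth = ground_truth(config, mesh)
        sites = sample_sites(config, mesh)
        bipole_sets, site_truth = synthesize_electrograms(
            mesh, truth, config, sites
        )
        bundle_io.write_bundle(
            bundle_dir, mesh, None, bipole_sets, truth,
            seed=config.seed, rhythm=config.rhythm,
            extra_manifest={"config_hash": config.content_hash()},
        )
        pd.DataFrame(
            {
                "site_id": np.arange(len(site_truth)),
                "true_lat_ms": site_truth["lat_ms"],
                "label": site_truth["label"],
            }
        ).to_csv(out_dir / "site_truth.csv", index=False)

    if "annotate" in stages:
        _require(bundle_dir / "manifest.json", "simulate")
        bundle = bundle_io.read_bundle(bundle_dir)
        st = None
        truth_csv = out_dir / "site_truth.csv"
        if truth_csv.exists():
            df = pd.read_csv(truth_csv)
            st = np.zeros(len(df), dtype=[("lat_ms", float), ("label", np.int64),
                                          ("on_conducting", bool)])
            st["lat_ms"] = df["true_lat_ms"]
            st["label"] = df["label"]
        points = annotate_bipole_sets(bundle.bipole_sets, st, ann_cfg)
        points.to_csv(out_dir / "annotations.csv", index=False)

    if "map" in stages:
        _require(out_dir / "annotations.csv", "annotate")
        bundle = bundle_io.read_bundle(bundle_dir)
        points = pd.read_csv(out_dir / "annotations.csv")
        amap = project_points(ActivationMap(bundle.mesh, points,
                                            rhythm=config.rhythm))
        amap = interpolate_lat(amap)
        ilam = build_ilam(amap)
        amap.points.to_csv(out_dir / "projected_points.csv", index=False)
        lat_csv = pd.DataFrame({"vertex": np.arange(bundle.mesh.n_vertices),
                                "lat_ms": amap.vertex_lat,
                                "iso_index": ilam.iso_index})
        lat_csv.to_csv(out_dir / "vertex_lat.csv", index=False)
        bundle_io.write_vtk(
            out_dir / "ilam.vtk", bundle.mesh,
            {"lat_ms": np.nan_to_num(amap.vertex_lat, nan=-1.0),
             "isochrone_index": ilam.iso_index},
        )
        summary = ilam.summary()
        summary.update(
            n_acquired=amap.n_acquired, n_used=amap.n_used,
            used_point_rate_pct=amap.used_point_rate(),
        )
        (out_dir / "map_summary.json").write_text(json.dumps(summary, indent=1))

    if "detect" in stages or "analyze" in stages or "validate" in stages:
        _require(out_dir / "vertex_lat.csv", "map")
        bundle = bundle_io.read_bundle(bundle_dir)
        points = pd.read_csv(out_dir / "projected_points.csv")
        df = pd.read_csv(out_dir / "vertex_lat.csv")
        amap = ActivationMap(bundle.mesh, points,
                             vertex_lat=df["lat_ms"].to_numpy(),
                             rhythm=config.rhythm)
        ilam = build_ilam(amap)

    if "detect" in stages:
        zones = detect_deceleration_zones(ilam, thresholds)
        for z in zones:
            flag_extreme_slowing(z, points, thresholds)
        blocks = detect_block_lines(ilam, points, thresholds)
        colls = detect_collisions(ilam)
        features = {
            "deceleration_zones": [
                {
                    "vertices": [int(v) for v in z.member_vertices],
                    "peak_isochrone_count": z.peak_isochrone_count,
                    "area_mm2": z.area_mm2,
                    "centroid": [float(c) for c in z.centroid],
                    "extreme": z.extreme,
                }
                for z in zones
            ],
            "block_lines": [
                {
                    "vertices": [int(v) for v in b.vertices],
                    "mean_gap_ms": None if np.isnan(b.mean_gap_ms)
                    else b.mean_gap_ms,
                    "reversal_confirmed": b.reversal_confirmed,
                }
                for b in blocks
            ],
            "collisions": [[int(v) for v in c] for c in colls],
        }
        (out_dir / "features.json").write_text(json.dumps(features, indent=1))

    if "analyze" in stages:
        _require(out_dir / "features.json", "detect")
        feats = json.loads((out_dir / "features.json").read_text())
        zones = detect_deceleration_zones(ilam, thresholds)  # cheap re-use
        isthmuses = delineate_isthmuses(bundle.mesh)
        for ai in isthmuses:
            try:
                analyze_isthmus(ai, ilam, zones)
            except ValueError as err:
                warnings.warn(f"{ai.ai_type}: {err}", stacklevel=2)
        isthmus_table(isthmuses).to_csv(out_dir / "isthmuses.csv", index=False)

    if "validate" in stages:
        _require(out_dir / "isthmuses.csv", "analyze")
        table = pd.read_csv(out_dir / "isthmuses.csv")
        if bundle.ground_truth is None or not bundle.ground_truth.corridors:
            report = {"status": "no truth available"}
        else:
            truth_sc = {
                c["ai_type"]: c["sc_true"] for c in bundle.ground_truth.corridors
            }
            table = table[table["ai_type"].isin(truth_sc)]
            try:
                rep = validation_report(
                    table["dz"].to_numpy(dtype=bool),
                    np.array([truth_sc[a] for a in table["ai_type"]]),
                    table["isochrones_per_cm"].to_numpy(dtype=float),
                    table["cv_m_s"].to_numpy(dtype=float),
                    seed=config.seed,
                )
                report = rep.as_dict()
            except ValueError as err:
                report = {"status": f"statistics unavailable: {err}",
                          "n": int(len(table))}
        (out_dir / "validation.json").write_text(json.dumps(report, indent=1))

    provenance = {
        "config_hash": config.content_hash(),
        "seed": int(config.seed),
        "stages": stages,
        "format_version": bundle_io.FORMAT_VERSION,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out_dir
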