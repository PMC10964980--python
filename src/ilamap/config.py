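"""Scenario configuration and seeded random substreams.

Units throughout the package: millimetres, milliseconds, millivolts.
Conduction velocity is stored in m/s, which is numerically equal to mm/ms.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

AI_TYPES = ("AI1", "AI2", "AI3", "AI4")

STRUCTURE_LABELS = (
    "tricuspid_annulus",
    "pulmonary_annulus",
    "vsd_patch",
    "rv_incision",
    "scar_patch",
)

#: label codes used on the mesh; 0 is conducting myocardium
LABEL_CODES = {name: i + 1 for i, name in enumerate(STRUCTURE_LABELS)}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}
MYOCARDIUM = 0

#: bounding non-conducting structures of each anatomical isthmus
AI_BOUNDS = {
    "AI1": ("tricuspid_annulus", "rv_incision"),
    "AI2": ("rv_incision", "pulmonary_annulus"),
    "AI3": ("vsd_patch", "pulmonary_annulus"),
    "AI4": ("vsd_patch", "tricuspid_annulus"),
}


def substream(seed: int, *names: str) -> np.random.Generator:
    """Derive a named, independent random substream from one root seed.

    Every stochastic draw in the package goes through a named substream so
    that a fixed root seed yields a bit-identical scenario regardless of the
    order in which stages are executed.
    """
    parts = [int(seed) & 0x7FFFFFFF]
    for name in names:
        h = hashlib.sha256(name.encode()).digest()
        parts.append(int.from_bytes(h[:4], "little"))
    return np.random.default_rng(parts)


@dataclass
class GeometryConfig:
    """Surface geometry: a developable 'opened RV' sheet, or a cylinder."""

    kind: str = "sheet"  # "sheet" | "cylinder"
    size_mm: tuple = (76.0, 44.0)  # (extent along x, extent along y)
    spacing_mm: float = 1.0


@dataclass
class StructureSpec:
    """A non-conducting region, placed as an axis-aligned rectangle (mm)."""

    label: str
    rect: tuple  # (x0, y0, x1, y1)

    def __post_init__(self):
        if self.label not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure label {self.label!r}")
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate rect for {self.label}: {self.rect}")


@dataclass
class CorridorSpec:
    """A conducting corridor between two structures with a planted CV."""

    ai_type: str
    width_mm: float
    planted_cv: float  # m/s

    def __post_init__(self):
        if self.ai_type not in AI_TYPES:
            raise ValueError(f"unknown AI type {self.ai_type!r}")
        if self.width_mm <= 0:
            raise ValueError("corridor width must be > 0")
        if self.planted_cv <= 0:
            raise ValueError("planted CV must be > 0")


@dataclass
class EgmConfig:
    """Bipolar electrogram synthesis parameters."""

    rate_hz: float = 2000.0
    noise_mV: float = 0.02
    n_bipoles: int = 4
    sensing_radius_mm: float = 5.0
    wavelet_sigma_ms: float = 0.8
    #: local activation spread that triggers fractionated extra wavelets
    fractionation_spread_ms: float = 18.0
    #: inter-cluster gap that produces a far-side (split) component
    split_gap_ms: float = 25.0
    normal_p2p_mV: tuple = (1.8, 6.0)
    farfield_p2p_mV: tuple = (0.15, 1.0)
    border_attenuation: tuple = (0.2, 0.6)
    border_zone_mm: float = 2.0


@dataclass
class ScenarioConfig:
    """Full description of one synthetic electroanatomical mapping study."""

    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    structures: list = field(default_factory=list)  # list[StructureSpec]
    corridors: list = field(default_factory=list)  # list[CorridorSpec]
    background_cv: float = 0.6  # m/s
    pacing_sources: list = field(default_factory=lambda: [((2.0, 22.0), 0.0)])
    point_density: float = 20.0  # sites per cm^2
    egm: EgmConfig = field(default_factory=EgmConfig)
    ablation_lines: list = field(default_factory=list)  # list of [(x, y), ...]
    rhythm: str = "paced"

    def validate(self) -> None:
        if self.point_density <= 0:
            raise ValueError("point_density must be > 0")
        if self.background_cv <= 0:
            raise ValueError("background_cv must be > 0")
        if self.egm.rate_hz < 1000:
            raise ValueError("electrogram rate must be >= 1000 Hz")
        if not self.pacing_sources:
            raise ValueError("at least one pacing source is required")
        for s in self.structures:
            if not isinstance(s, StructureSpec):
                raise TypeError("structures must be StructureSpec instances")
        for c in self.corridors:
            if not isinstance(c, CorridorSpec):
                raise TypeError("corridors must be CorridorSpec instances")

    # ------------------------------------------------------------------ IO
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["geometry"] = GeometryConfig(**d.get("geometry", {}))
        d["egm"] = EgmConfig(**d.get("egm", {}))
        d["structures"] = [
            s if isinstance(s, StructureSpec) else StructureSpec(**s)
            for s in d.get("structures", [])
        ]
        d["corridors"] = [
            c if isinstance(c, CorridorSpec) else CorridorSpec(**c)
            for c in d.get("corridors", [])
        ]
        # YAML round-trips tuples as lists
        d["geometry"].size_mm = tuple(d["geometry"].size_mm)
        d["pacing_sources"] = [
            (tuple(pos), float(t0)) for pos, t0 in d.get("pacing_sources", [])
        ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples/numpy scalars so YAML stays clean."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
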