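"""Electrogram-level computations.

Best-bipole selection for grid-catheter sites, deflection detection,
last-deflection local activation time (LAT) annotation, split-potential and
fractionation scoring, and bipolar voltage classification.

Conventions: an electrogram deflection is a maximal run of samples whose
absolute slope reaches the significance threshold (runs separated by less
than ``merge_gap_ms`` are merged, so the zero-slope instants at wavelet
extrema do not fragment one deflection) and whose voltage excursion exceeds
the noise floor.  The LAT of a site is the offset of the *last* deflection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class Electrogram:
    samples: np.ndarray  # mV
    rate_hz: float
    t0_ms: float = 0.0
    orientation: str = "along"  # "along" | "across" the catheter splines

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz < 1000:
            raise ValueError("electrogram rate must be >= 1000 Hz")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("electrogram samples must be finite")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.samples)) * self.dt_ms

    def peak_to_peak(self) -> float:
        if len(self.samples) == 0:
            return 0.0
        return float(self.samples.max() - self.samples.min())


@dataclass
class BipoleSet:
    """One acquisition site: orthogonal bipolar electrograms, 3 mm spacing."""

    site_position: np.ndarray  # (3,) mm
    bipoles: list  # list[Electrogram]
    spacing_mm: float = 3.0

    def __post_init__(self):
        if self.spacing_mm <= 0:
            raise ValueError("bipole spacing must be > 0")


@dataclass
class AnnotationConfig:
    """Deflection-significance and classification thresholds.

    ``split_gap_ms`` (isoelectric gap, strict >) and ``voltage_abnormal_mV``
    (strict <) are the published constants; ``dense_scar_mV`` is the
    conventional 0.5 mV surrogate for pacing-confirmed unexcitable scar.
    """

    noise_floor_mV: float = 0.05
    deflection_min_slope: float = 0.1  # mV/ms
    split_gap_ms: float = 20.0
    voltage_abnormal_mV: float = 1.5
    dense_scar_mV: float = 0.5
    fractionation_min_deflections: int = 4
    merge_gap_ms: float = 2.0
    smooth_samples: int = 1

    def __post_init__(self):
        for name in ("noise_floor_mV", "deflection_min_slope", "split_gap_ms",
                     "voltage_abnormal_mV", "dense_scar_mV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Annotation:
    lat_ms: float = np.nan  # offset of the latest deflection
    voltage_mV: float = 0.0  # peak-to-peak of the selected bipole
    split: bool = False
    gap_ms: float = 0.0
    n_deflections: int = 0
    used: bool = False


def select_best_bipole(bs: BipoleSet) -> tuple:
    """Largest peak-to-peak amplitude among all bipoles of a site.

    Ties resolve to the lowest bipole index.  Returns (electrogram, voltage).
    """
    if not bs.bipoles:
        raise ValueError("empty bipole set")
    amps = np.array([b.peak_to_peak() for b in bs.bipoles])
    k = int(np.argmax(amps))
    return bs.bipoles[k], float(amps[k])


def detect_deflections(egm: Electrogram, cfg: AnnotationConfig) -> list:
    """Disjoint deflection intervals, sorted by onset.

    A deflection is a run where |slope| >= ``deflection_min_slope`` (after a
    centred moving-average of ``smooth_samples``), merged across gaps shorter
    than ``merge_gap_ms``, with sample excursion >= ``noise_floor_mV``.
    Returns a list of dicts with ``onset_ms``, ``peak_ms``, ``offset_ms``.
    """
    x = egm.samples
    if len(x) < 3:
        return []
    if cfg.smooth_samples > 1:
        k = int(cfg.smooth_samples)
        xs = np.convolve(x, np.ones(k) / k, mode="same")
    else:
        xs = x
    slope = np.gradient(xs) / egm.dt_ms
    active = np.abs(slope) >= cfg.deflection_min_slope
    if not active.any():
        return []

    idx = np.flatnonzero(active)
    max_gap = max(1, int(round(cfg.merge_gap_ms / egm.dt_ms)))
    breaks = np.flatnonzero(np.diff(idx) > max_gap)
    runs = np.split(idx, breaks + 1)

    t = egm.times_ms
    out = []
    for run in runs:
        i0, i1 = int(run[0]), int(run[-1])
        seg = x[i0 : i1 + 1]
        if seg.max() - seg.min() < cfg.noise_floor_mV:
            continue
        peak = i0 + int(np.argmax(np.abs(seg)))
        out.append(
            {"onset_ms": float(t[i0]), "peak_ms": float(t[peak]),
             "offset_ms": float(t[i1])}
        )
    return out


def annotate_last_deflection(egm: Electrogram, cfg: AnnotationConfig) -> Annotation:
    """Annotate the offset of the latest deflection (the site's LAT).

    A split potential is flagged when the isoelectric gap between consecutive
    deflections strictly exceeds ``split_gap_ms``.  With no detectable
    deflection the annotation comes back with ``used=False``.
    """
    defl = detect_deflections(egm, cfg)
    if not defl:
        return Annotation(used=False)
    gaps = [
        b["onset_ms"] - a["offset_ms"] for a, b in zip(defl[:-1], defl[1:])
    ]
    gap = max(gaps) if gaps else 0.0
    return Annotation(
        lat_ms=defl[-1]["offset_ms"],
        voltage_mV=egm.peak_to_peak(),
        split=gap > cfg.split_gap_ms,
        gap_ms=float(gap),
        n_deflections=len(defl),
        used=True,
    )


def classify_voltage(voltage_mV: float, cfg: Optional[AnnotationConfig] = None) -> str:
    """Bipolar voltage class: normal / abnormal (<1.5 mV) / dense_scar (<0.5 mV)."""
    cfg = cfg or AnnotationConfig()
    if voltage_mV < 0:
        raise ValueError("voltage must be >= 0")
    if voltage_mV < cfg.dense_scar_mV:
        return "dense_scar"
    if voltage_mV < cfg.voltage_abnormal_mV:
        return "abnormal"
    return "normal"


def fractionation_score(egm: Electrogram, cfg: AnnotationConfig) -> dict:
    """Deflection count, active duration and the fractionated flag."""
    defl = detect_deflections(egm, cfg)
    duration = defl[-1]["offset_ms"] - defl[0]["onset_ms"] if defl else 0.0
    return {
        "n_deflections": len(defl),
        "duration_ms": float(duration),
        "fractionated": len(defl) >= cfg.fractionation_min_deflections,
    }


def annotate_site(bs: BipoleSet, cfg: Optional[AnnotationConfig] = None) -> Annotation:
    """Full site annotation: best-bipole selection then last-deflection LAT."""
    cfg = cfg or AnnotationConfig()
    best, voltage = select_best_bipole(bs)
    ann = annotate_last_deflection(best, cfg)
    ann.voltage_mV = voltage
    return ann
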