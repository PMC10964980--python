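"""Shared fixtures: representative synthetic studies, computed once."""
import numpy as np
import pytest

import ilamap as il


@pytest.fixture(scope="session")
def slow_corridor_result():
    """Single AI3 corridor with planted CV 0.15 m/s (slow conduction)."""
    return il.analyze_scenario(il.corridor_scenario(planted_cv=0.15, seed=3))


@pytest.fixture(scope="session")
def fast_corridor_result():
    """Single AI1 corridor with planted CV 1.25 m/s (normal conduction)."""
    return il.analyze_scenario(
        il.corridor_scenario(planted_cv=1.25, ai_type="AI1", seed=5)
    )


@pytest.fixture(scope="session")
def default_map_result():
    """Four-isthmus repaired-TOF-like map."""
    return il.analyze_scenario(il.default_rtf_scenario(seed=1))


@pytest.fixture(scope="session")
def validation_cohort():
    """28 corridors, planted CVs uniform on [0.1, 1.5] m/s, noiseless,
    20 sites/cm^2 — the study conditions of the recovery properties."""
    return il.corridor_cohort(n_corridors=28, seed=0)


@pytest.fixture
def ann_cfg():
    return il.AnnotationConfig()


def triangular_pulse(t, onset, offset, amplitude=1.0):
    """Piecewise-linear biphasic-ish pulse with exact onset/offset times."""
    mid = 0.5 * (onset + offset)
    up = np.clip((t - onset) / (mid - onset), 0, 1)
    down = np.clip((offset - t) / (offset - mid), 0, 1)
    return amplitude * np.minimum(up, down)


@pytest.fixture
def make_pulse_egm():
    """Factory: electrogram with pulses at exact (onset, offset) intervals."""

    def _make(intervals, rate_hz=2000.0, t0=0.0, duration=None, amplitude=1.0):
        duration = duration or (max(o for _, o in intervals) + 20.0)
        n = int(round((duration - t0) * rate_hz / 1000.0)) + 1
        t = t0 + np.arange(n) * 1000.0 / rate_hz
        x = np.zeros(n)
        for onset, offset in intervals:
            x += triangular_pulse(t, onset, offset, amplitude)
        return il.Electrogram(samples=x, rate_hz=rate_hz, t0_ms=t0)

    return _make
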