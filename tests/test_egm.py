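"""Electrogram processing: bipole selection, deflections, annotation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ilamap as il
from ilamap.egm import (
    AnnotationConfig,
    BipoleSet,
    Electrogram,
    annotate_last_deflection,
    classify_voltage,
    detect_deflections,
    fractionation_score,
    select_best_bipole,
)


def _egm_with_p2p(p2p, n=40, rate=2000.0):
    x = np.zeros(n)
    x[10] = p2p / 2
    x[12] = -p2p / 2
    return Electrogram(samples=x, rate_hz=rate)


# ------------------------------------------------------------ best bipole
def test_select_best_bipole_picks_max_amplitude():
    bs = BipoleSet(np.zeros(3), [_egm_with_p2p(a) for a in (0.8, 2.0, 1.1)])
    egm, v = select_best_bipole(bs)
    assert v == pytest.approx(2.0)
    assert egm is bs.bipoles[1]


def test_select_best_bipole_tie_takes_lowest_index():
    bs = BipoleSet(np.zeros(3), [_egm_with_p2p(a) for a in (1.5, 1.5, 0.5)])
    egm, _ = select_best_bipole(bs)
    assert egm is bs.bipoles[0]


def test_select_best_bipole_empty_raises():
    with pytest.raises(ValueError, match="empty"):
        select_best_bipole(BipoleSet(np.zeros(3), []))


@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=24),
       st.randoms(use_true_random=False))
@settings(max_examples=50, deadline=None)
def test_selection_equals_bruteforce_argmax_under_permutation(amps, rnd):
    """Permutation-invariant up to the documented lowest-index tie-break."""
    rnd.shuffle(amps)
    bs = BipoleSet(np.zeros(3), [_egm_with_p2p(a) for a in amps])
    egm, v = select_best_bipole(bs)
    best = max(range(len(amps)), key=lambda k: (amps[k], -k))
    assert v == pytest.approx(bs.bipoles[best].peak_to_peak())
    assert egm is bs.bipoles[best]


# ------------------------------------------------------------- deflections
def test_flat_signal_has_no_deflections(ann_cfg):
    egm = Electrogram(samples=np.zeros(100), rate_hz=2000.0)
    assert detect_deflections(egm, ann_cfg) == []
    ann = annotate_last_deflection(egm, ann_cfg)
    assert not ann.used


def test_two_pulses_found_at_construction_times(make_pulse_egm, ann_cfg):
    egm = make_pulse_egm([(48.0, 54.0), (88.0, 94.0)])
    defl = detect_deflections(egm, ann_cfg)
    assert len(defl) == 2
    dt = egm.dt_ms
    assert defl[0]["onset_ms"] == pytest.approx(48.0, abs=dt)
    assert defl[0]["offset_ms"] == pytest.approx(54.0, abs=dt)
    assert defl[1]["onset_ms"] == pytest.approx(88.0, abs=dt)


def _oracle_scan(egm, cfg):
    """Naive loop implementing the deflection contract directly."""
    x = egm.samples
    if cfg.smooth_samples > 1:
        k = cfg.smooth_samples
        x = np.convolve(x, np.ones(k) / k, mode="same")
    slope = np.gradient(x) / egm.dt_ms
    active = [i for i in range(len(x)) if abs(slope[i]) >= cfg.deflection_min_slope]
    if not active:
        return 0
    gap = max(1, int(round(cfg.merge_gap_ms / egm.dt_ms)))
    runs, cur = [], [active[0]]
    for i in active[1:]:
        if i - cur[-1] > gap:
            runs.append(cur)
            cur = [i]
        else:
            cur.append(i)
    runs.append(cur)
    count = 0
    for r in runs:
        seg = egm.samples[r[0] : r[-1] + 1]
        if seg.max() - seg.min() >= cfg.noise_floor_mV:
            count += 1
    return count


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("min_slope", [0.05, 0.1, 0.3])
def test_deflection_count_matches_threshold_scan_oracle(seed, min_slope):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(0, 0.05, size=400))
    egm = Electrogram(samples=x, rate_hz=2000.0)
    cfg = AnnotationConfig(deflection_min_slope=min_slope)
    assert len(detect_deflections(egm, cfg)) == _oracle_scan(egm, cfg)


# -------------------------------------------------------------- annotation
def test_lat_is_offset_of_latest_deflection(make_pulse_egm, ann_cfg):
    egm = make_pulse_egm([(54.0, 60.0), (94.0, 100.0)])
    ann = annotate_last_deflection(egm, ann_cfg)
    assert ann.used
    assert ann.lat_ms == pytest.approx(100.0, abs=egm.dt_ms)
    assert ann.n_deflections == 2


def test_isoelectric_gap_over_20ms_is_split(make_pulse_egm, ann_cfg):
    egm = make_pulse_egm([(30.0, 40.0), (65.0, 75.0)])  # gap 25 ms
    ann = annotate_last_deflection(egm, ann_cfg)
    assert ann.split
    assert ann.gap_ms == pytest.approx(25.0, abs=2 * egm.dt_ms)


def test_gap_exactly_20ms_is_not_split(make_pulse_egm, ann_cfg):
    egm = make_pulse_egm([(30.0, 40.0), (60.0, 70.0)])  # gap exactly 20 ms
    ann = annotate_last_deflection(egm, ann_cfg)
    assert not ann.split


@pytest.mark.parametrize("gap", [22.0, 30.0, 60.0, 110.0])
def test_split_detection_is_monotone_in_gap(make_pulse_egm, ann_cfg, gap):
    """If a gap g is detected as split, any larger gap is too."""
    egm = make_pulse_egm([(30.0, 40.0), (40.0 + gap, 50.0 + gap)])
    assert annotate_last_deflection(egm, ann_cfg).split


# ----------------------------------------------------------------- voltage
@pytest.mark.parametrize(
    "v,expected",
    [(1.6, "normal"), (1.5, "normal"), (1.49, "abnormal"),
     (0.5, "abnormal"), (0.2, "dense_scar")],
)
def test_voltage_classes_with_strict_thresholds(v, expected):
    assert classify_voltage(v) == expected


def test_negative_voltage_rejected():
    with pytest.raises(ValueError):
        classify_voltage(-0.1)


# ------------------------------------------------------------ fractionation
def test_single_pulse_is_not_fractionated(make_pulse_egm, ann_cfg):
    egm = make_pulse_egm([(50.0, 56.0)])
    score = fractionation_score(egm, ann_cfg)
    assert score["n_deflections"] == 1
    assert not score["fractionated"]


def test_five_pulses_over_80ms_are_fractionated(make_pulse_egm, ann_cfg):
    intervals = [(20.0 + 18 * k, 26.0 + 18 * k) for k in range(5)]
    score = fractionation_score(egm := make_pulse_egm(intervals), ann_cfg)
    assert score["n_deflections"] == 5
    assert score["fractionated"]
    assert score["duration_ms"] == pytest.approx(78.0, abs=2 * egm.dt_ms)


def test_flat_signal_scores_zero(ann_cfg):
    egm = Electrogram(samples=np.zeros(200), rate_hz=2000.0)
    assert fractionation_score(egm, ann_cfg)["n_deflections"] == 0
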