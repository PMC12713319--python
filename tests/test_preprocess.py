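import numpy as np
import pandas as pd
import pytest

from cbpupil.datatypes import PupilRecording, make_event_table
from cbpupil.preprocess import (IRFParams, apply_qc, bandpass_filter,
                                downsample, epoch, interpolate_blinks,
                                pupil_irf, regress_nuisance, standardize)

NO_EVENTS = make_event_table([], [], [])


def _rec(pupil, rate=1000.0, valid=None, stage="raw"):
    pupil = np.asarray(pupil, dtype=float)
    valid = np.ones(len(pupil), bool) if valid is None else np.asarray(valid)
    return PupilRecording(t=np.arange(len(pupil)) / rate, pupil=pupil,
                          rate=rate, valid=valid, stage_tag=stage)


# ---------------------------------------------------------------------------
# interpolation

def test_interpolate_flat_neighbors():
    rec = _rec([2, 2, 0, 0, 2, 2], rate=1.0,
               valid=[True, True, False, False, True, True])
    out = interpolate_blinks(rec, NO_EVENTS, pad_ms=150)
    np.testing.assert_allclose(out.pupil, 2.0)
    assert list(out.valid) == [True, True, False, False, True, True]
    assert out.stage_tag == "interpolated"


def test_interpolate_edge_gap_constant_extension():
    rec = _rec([0, 0, 5, 5], rate=1.0, valid=[False, False, True, True])
    out = interpolate_blinks(rec, NO_EVENTS, pad_ms=100)
    np.testing.assert_allclose(out.pupil, [5, 5, 5, 5])


def test_interpolate_pads_blink_by_150ms():
    """A 200 ms blink padded by 150 ms on each side invalidates exactly
    500 ms of samples at 1000 Hz."""
    n = 2000
    pupil = np.ones(n)
    rec = _rec(pupil, rate=1000.0)
    ev = make_event_table(["blink"], [800], [1000])
    out = interpolate_blinks(rec, ev, pad_ms=150)
    assert int((~out.valid).sum()) == 500
    t_ms = np.rint(out.t * 1000).astype(int)
    assert set(t_ms[~out.valid]) == set(range(650, 1150))


def test_interpolate_all_invalid_errors():
    rec = _rec([0, 0, 0], rate=1.0, valid=[False] * 3)
    with pytest.raises(ValueError, match="entirely invalid"):
        interpolate_blinks(rec, NO_EVENTS)


# ---------------------------------------------------------------------------
# band-pass

def test_filter_removes_dc():
    rec = _rec(np.full(600_000, 7.0), stage="interpolated")
    out = bandpass_filter(rec)
    assert np.abs(out.pupil).max() < 1e-6


def test_filter_passband_and_stopband():
    rate, dur = 1000.0, 600.0
    t = np.arange(int(rate * dur)) / rate
    one_hz = bandpass_filter(_rec(np.sin(2 * np.pi * 1.0 * t),
                                  stage="interpolated"))
    mid = one_hz.pupil[len(t) // 4: 3 * len(t) // 4]
    assert 0.9 <= np.abs(mid).max() <= 1.0
    twenty_hz = bandpass_filter(_rec(np.sin(2 * np.pi * 20.0 * t),
                                     stage="interpolated"))
    assert np.abs(twenty_hz.pupil[len(t) // 4: 3 * len(t) // 4]).max() < 0.05


def test_filter_rejects_cutoff_beyond_nyquist():
    rec = _rec(np.ones(1000), rate=100.0, stage="interpolated")
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_filter(rec, low=0.02, high=60.0)


# ---------------------------------------------------------------------------
# standardization

def test_standardize_unit_sd_and_scale_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 3.7, 10_000)
    a = standardize(_rec(x, stage="filtered"))
    assert np.std(a.pupil[a.valid]) == pytest.approx(1.0, abs=1e-9)
    b = standardize(_rec(7 * x, stage="filtered"))
    np.testing.assert_allclose(a.pupil, b.pupil, atol=1e-12)
    assert b.scale == pytest.approx(7 * a.scale)
    # idempotent: unit-SD input is returned unchanged
    again = a.copy()
    again.stage_tag = "filtered"
    c = standardize(again)
    np.testing.assert_allclose(c.pupil, a.pupil, atol=1e-12)


def test_standardize_zero_variance_errors():
    with pytest.raises(ValueError, match="variance"):
        standardize(_rec(np.zeros(100), stage="filtered"))


# ---------------------------------------------------------------------------
# downsampling

def test_downsample_length_mask_and_amplitude():
    rng = np.random.default_rng(1)
    n = 100_003
    valid = np.ones(n, bool)
    valid[15] = False       # one invalid sample in block 1
    rec = _rec(rng.normal(size=n), valid=valid, stage="standardized")
    out = downsample(rec, 100.0)
    assert len(out) == int(np.ceil(n / 10))
    assert not out.valid[1]
    assert out.valid[0] and out.valid[2]
    assert out.native_rate == 1000.0 and len(out.native_valid) == n

    t = np.arange(600_000) / 1000.0
    sine = _rec(np.sin(2 * np.pi * 1.0 * t), stage="standardized")
    dec = downsample(sine, 100.0)
    assert np.abs(dec.pupil).max() == pytest.approx(1.0, rel=0.01)


def test_downsample_non_integer_ratio_errors():
    rec = _rec(np.ones(100), rate=1000.0, stage="standardized")
    with pytest.raises(ValueError, match="integer multiple"):
        downsample(rec, 300.0)


# ---------------------------------------------------------------------------
# canonical kernel

def test_irf_shape_properties():
    p = IRFParams()
    for rate in (100.0, 1000.0):
        h = pupil_irf(p, rate)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        assert abs(h.argmax() / rate - p.t_max) <= 1.0 / rate


def test_irf_matches_closed_form_at_half_peak_time():
    p = IRFParams(w=10.1, t_max=0.93)
    rate = 100.0
    h = pupil_irf(p, rate)
    t = 0.5 * p.t_max
    # direct formula, normalized by the peak value t_max^w * exp(-w)
    expected = (t ** p.w * np.exp(-p.w * t / p.t_max)) / \
               (p.t_max ** p.w * np.exp(-p.w))
    assert expected == pytest.approx(0.5 ** 10.1 * np.exp(5.05))
    k = int(round(t * rate))
    assert h[k] == pytest.approx((k / rate) ** p.w * np.exp(-p.w * (k / rate) / p.t_max)
                                 / (p.t_max ** p.w * np.exp(-p.w)))


# ---------------------------------------------------------------------------
# nuisance regression

def _target_rec(pupil, rate=100.0):
    return PupilRecording(t=np.arange(len(pupil)) / rate, pupil=pupil,
                          rate=rate, valid=np.ones(len(pupil), bool),
                          stage_tag="downsampled")


def test_regression_removes_pure_blink_response():
    rate, n = 100.0, 6000
    kernel = pupil_irf(IRFParams(), rate)
    ends = [5000, 20_000, 41_000]   # ms
    train = np.zeros(n)
    for e in ends:
        train[int(e / 1000 * rate)] = 1.0
    sig = np.convolve(train, kernel)[:n] * 2.5
    rec = _target_rec(sig)
    ev = make_event_table(["blink"] * 3, [e - 120 for e in ends], ends)
    out = regress_nuisance(rec, ev)
    assert np.abs(out.pupil).max() < 1e-8


def test_regression_without_events_is_passthrough():
    rec = _target_rec(np.sin(np.arange(1000) / 50))
    with pytest.warns(UserWarning, match="pass-through"):
        out = regress_nuisance(rec, NO_EVENTS)
    np.testing.assert_array_equal(out.pupil, rec.pupil)
    assert out.stage_tag == "nuisance_regressed"


def test_regression_halves_artifact_error():
    """Task responses plus blink artifacts: regression must reduce the RMS
    deviation from the pure task trace by at least half."""
    rate, n = 100.0, 12_000
    kernel = pupil_irf(IRFParams(), rate)
    task_train = np.zeros(n)
    for onset_s in (10, 35, 60, 85, 110):
        task_train[int(onset_s * rate)] = 1.0
    task = np.convolve(task_train, kernel)[:n]
    blink_ends = [20_000, 50_000, 95_000]
    blink_train = np.zeros(n)
    for e in blink_ends:
        blink_train[int(e / 1000 * rate)] = 1.0
    artifact = np.convolve(blink_train, kernel)[:n] * 1.5
    rec = _target_rec(task + artifact)
    ev = make_event_table(["blink"] * 3, [e - 150 for e in blink_ends],
                          blink_ends)
    out = regress_nuisance(rec, ev)
    rms_before = np.sqrt(np.mean((rec.pupil - task) ** 2))
    rms_after = np.sqrt(np.mean((out.pupil - task) ** 2))
    assert rms_after <= 0.5 * rms_before


# ---------------------------------------------------------------------------
# epoching

def _epoch_ready(pupil, rate=100.0):
    return PupilRecording(t=np.arange(len(pupil)) / rate, pupil=pupil,
                          rate=rate, valid=np.ones(len(pupil), bool),
                          stage_tag="nuisance_regressed")


def _one_trial_table(onset_s):
    return pd.DataFrame([dict(trial_idx=1, condition="M", test_onset_s=onset_s)])


def test_epoch_constant_trace_is_zero():
    rec = _epoch_ready(np.full(3000, 4.2))
    ep = epoch(rec, _one_trial_table(10.0))
    assert ep.data.shape == (1, 601)
    np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)


def test_epoch_sample_arithmetic():
    rec = _epoch_ready(np.zeros(3000))
    ep = epoch(rec, _one_trial_table(10.0))
    assert len(ep.times) == 601
    assert ep.times[100] == pytest.approx(0.0)
    assert ep.times[0] == pytest.approx(-1.0) and ep.times[-1] == pytest.approx(5.0)


def test_epoch_of_pure_kernel_reproduces_kernel():
    rate = 100.0
    kernel = pupil_irf(IRFParams(), rate)
    sig = np.zeros(3000)
    onset = 10.0
    i0 = int(onset * rate)
    sig[i0:i0 + len(kernel)] = kernel
    ep = epoch(_epoch_ready(sig), _one_trial_table(onset))
    expected = np.zeros(601)
    expected[100:100 + len(kernel)] = kernel
    np.testing.assert_allclose(ep.data[0], expected, atol=1e-12)


def test_epoch_near_edge_marks_trial_excluded():
    rec = _epoch_ready(np.zeros(300))
    with pytest.warns(UserWarning, match="outside"):
        ep = epoch(rec, _one_trial_table(0.5))
    assert not ep.included[0]
    assert ep.invalid_fraction[0] == 1.0


# ---------------------------------------------------------------------------
# QC

def _epochs_with_invalid(fracs):
    n = len(fracs)
    from cbpupil.datatypes import EpochSet
    return EpochSet(data=np.zeros((n, 601)), times=-1 + np.arange(601) / 100,
                    trial_keys=np.arange(1, n + 1),
                    invalid_fraction=np.asarray(fracs, float),
                    included=np.ones(n, bool), rate=100.0)


def test_qc_boundary_exactly_two_seconds_retained():
    ep, verdict = apply_qc(_epochs_with_invalid([2000 / 6000, 2001 / 6000]))
    assert ep.included[0]           # exactly one third: kept
    assert not ep.included[1]       # strictly more: excluded
    assert verdict.n_excluded == 1


def test_qc_subject_excluded_at_half_the_trials():
    fracs = [0.9] * 15 + [0.0] * 15
    _, verdict = apply_qc(_epochs_with_invalid(fracs))
    assert verdict.n_excluded == 15
    assert verdict.subject_excluded
    _, ok = apply_qc(_epochs_with_invalid([0.9] * 14 + [0.0] * 16))
    assert not ok.subject_excluded


# ---------------------------------------------------------------------------
# stage-order contract

def test_stages_refuse_out_of_order_input():
    raw = _rec(np.ones(1000))
    with pytest.raises(ValueError, match="order violation"):
        bandpass_filter(raw)
    with pytest.raises(ValueError, match="order violation"):
        standardize(raw)
    with pytest.raises(ValueError, match="order violation"):
        downsample(raw)
    filtered = _rec(np.ones(1000), stage="filtered")
    with pytest.raises(ValueError, match="order violation"):
        interpolate_blinks(filtered, NO_EVENTS)
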