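"""Unit and property tests for the preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsnet import (
    Event,
    MbllCoefficients,
    RawRecording,
    TrialLog,
    bandpass,
    behavioral_summary,
    block_average,
    detect_motion,
    intensity_to_od,
    mbll,
    spline_correct,
    subject_activation,
    zscore,
)
from nirsnet.preprocess import HemoTimeSeries, OpticalDensitySeries

FS = 50.0


def _recording(intensity, events=()):
    n_ch = intensity.shape[0]
    return RawRecording(
        subject_id="t", group="TD", fs=FS,
        channels=[f"CH{i:02d}" for i in range(1, n_ch + 1)],
        wavelengths_nm=(690.0, 830.0),
        intensity=intensity, events=list(events),
    )


def _od(arr):
    n_ch = arr.shape[0]
    return OpticalDensitySeries(
        od=arr, fs=FS,
        channels=[f"CH{i:02d}" for i in range(1, n_ch + 1)],
        wavelengths_nm=(690.0, 830.0),
    )


# ---------------------------------------------------------------- OD

def test_od_of_constant_intensity_is_zero():
    rec = _recording(np.full((2, 2, 100), 1.7))
    od = intensity_to_od(rec)
    assert np.allclose(od.od, 0.0)


def test_od_log_definition_and_scale_invariance():
    i = np.ones(100)
    i[10] = np.exp(-1.0)  # dips to mean * e^-1, so OD there approaches 1
    intensity = np.empty((1, 2, 100))
    intensity[0, 0] = 3.0 * i  # uniform rescaling must not change OD
    intensity[0, 1] = i
    od = intensity_to_od(_recording(intensity))
    expected = -np.log(i / i.mean())
    assert np.allclose(od.od[0, 0], expected)
    assert np.allclose(od.od[0, 0], od.od[0, 1])


# ---------------------------------------------------------------- motion

def test_subthreshold_sinusoid_yields_empty_mask():
    t = np.arange(0, 60, 1 / FS)
    x = 0.01 * np.sin(2 * np.pi * 0.05 * t)
    od = _od(np.tile(x, (1, 2, 1)))
    mask = detect_motion(od, amp_threshold=0.5)
    assert not mask.any()
    # all-constant series likewise
    assert not detect_motion(_od(np.zeros((1, 2, 3000)))).any()


def test_large_step_is_flagged_around_its_onset():
    t = np.arange(0, 60, 1 / FS)
    x = 0.01 * np.sin(2 * np.pi * 0.03 * t)
    x[1500:] += 5.0  # 10x the amplitude threshold
    od = _od(np.tile(x, (1, 2, 1)))
    mask = detect_motion(od, amp_threshold=0.5)
    assert mask[0, 1500]
    assert mask[0, 1475:1525].all()


def test_spline_correction_noop_and_step_removal():
    t = np.arange(0, 120, 1 / FS)
    clean = 0.005 * np.sin(2 * np.pi * 0.04 * t)
    od = _od(np.tile(clean, (1, 2, 1)))
    empty = np.zeros((1, len(t)), dtype=bool)
    assert spline_correct(od, empty) is od

    amp = 0.5
    contaminated = clean.copy()
    contaminated[3000:] += amp
    od2 = _od(np.tile(contaminated, (1, 2, 1)))
    mask = detect_motion(od2, amp_threshold=0.25)
    assert mask.any()
    fixed = spline_correct(od2, mask)
    before = fixed.od[0, 0, 2900:2950].mean()
    after = fixed.od[0, 0, 3100:3150].mean()
    assert abs(after - before) < 0.1 * amp


def test_spline_correction_reduces_spike_variance():
    t = np.arange(0, 120, 1 / FS)
    clean = 0.005 * np.sin(2 * np.pi * 0.04 * t)
    spike = clean.copy()
    spike[3000:3050] += 0.8 * np.exp(-np.arange(50) / 10.0)
    od = _od(np.tile(spike, (1, 2, 1)))
    mask = detect_motion(od, amp_threshold=0.25)
    fixed = spline_correct(od, mask)
    assert fixed.od[0, 0].var() < spike.var()


# ---------------------------------------------------------------- band-pass

def _sine_attenuation(freq):
    t = np.arange(0, 1200, 1 / FS)
    x = np.sin(2 * np.pi * freq * t)
    od = _od(np.tile(x, (1, 2, 1)))
    y = bandpass(od).od[0, 0]
    # the 0.01 Hz edge rings for minutes; measure steady state only
    sel = slice(int(300 * FS), int(900 * FS))
    return np.abs(y[sel]).max()


def test_passband_center_preserved_and_cardiac_rejected():
    assert _sine_attenuation(0.05) == pytest.approx(1.0, abs=0.05)
    assert _sine_attenuation(1.0) < 10 ** (-20 / 20)  # >= 20 dB down
    # constant offset is removed entirely
    dc = bandpass(_od(np.full((1, 2, 30_000), 3.0))).od
    assert np.abs(dc).max() < 1e-6


def test_bandpass_rejects_misordered_cutoffs():
    od = _od(np.zeros((1, 2, 1000)))
    with pytest.raises(ValueError):
        bandpass(od, 0.1, 0.01)


# ---------------------------------------------------------------- MBLL

def test_mbll_linearity_and_forward_round_trip():
    coef = MbllCoefficients()
    m = coef.matrix()
    target = np.array([1e-6, -5e-7])
    d_a = coef.separation_cm * (m @ target)
    od = _od(np.zeros((1, 2, 3)))
    od.od[0, :, :] = d_a[:, None]
    h = mbll(od, coef)
    assert h.hbo[0] == pytest.approx(target[0], rel=1e-12)
    assert h.hbr[0] == pytest.approx(target[1], rel=1e-12)
    # zero maps to zero; doubling input doubles output
    zero = mbll(_od(np.zeros((1, 2, 3))), coef)
    assert np.all(zero.hbo == 0) and np.all(zero.hbr == 0)
    od2 = _od(2 * od.od.copy())
    h2 = mbll(od2, coef)
    assert np.allclose(h2.hbo, 2 * h.hbo) and np.allclose(h2.hbr, 2 * h.hbr)


def test_mbll_singular_matrix_rejected():
    coef = MbllCoefficients(extinction={690.0: (1.0, 1.0), 830.0: (1.0, 1.0)})
    with pytest.raises(np.linalg.LinAlgError):
        coef.matrix()


# ---------------------------------------------------------------- z-score

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 50.0),
    offset=st.floats(-10.0, 10.0),
    seed=st.integers(0, 1000),
)
def test_zscore_affine_invariance(scale, offset, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((3, 400))
    h = HemoTimeSeries(hbo=x, hbr=-x, fs=FS, channels=["a", "b", "c"])
    h2 = HemoTimeSeries(
        hbo=scale * x + offset, hbr=-(scale * x + offset), fs=FS,
        channels=["a", "b", "c"],
    )
    z1, z2 = zscore(h), zscore(h2)
    assert np.allclose(z1.hbo, z2.hbo, atol=1e-9)
    assert np.abs(z1.hbo.mean(axis=1)).max() < 1e-10
    assert np.abs(z1.hbo.var(axis=1) - 1).max() < 1e-8
    # idempotent
    assert np.allclose(zscore(z1).hbo, z1.hbo, atol=1e-10)


def test_zscore_rejects_constant_channel():
    h = HemoTimeSeries(
        hbo=np.vstack([np.ones(100), np.arange(100.0)]),
        hbr=np.zeros((2, 100)), fs=FS, channels=["CH01", "CH02"],
    )
    h.hbr = np.vstack([np.arange(100.0), np.arange(100.0)])
    with pytest.raises(ValueError, match="CH01"):
        zscore(h)


# ---------------------------------------------------------------- epochs

def _hemo(hbo, events):
    return HemoTimeSeries(
        hbo=hbo, hbr=-0.3 * hbo, fs=FS,
        channels=[f"CH{i:02d}" for i in range(1, hbo.shape[0] + 1)],
        events=events,
    )


def test_block_average_of_identical_epochs_recovers_one_epoch():
    n = int(40 * FS)
    template = np.zeros(int(17 * FS))
    template[int(2 * FS):int(7 * FS)] = 1.0  # boxcar after onset
    hbo = np.zeros((1, n))
    onsets = [5.0, 22.0]
    for o in onsets:
        i0 = int(o * FS) - int(2 * FS)
        hbo[0, i0:i0 + len(template)] = template
    events = [Event(o, 1, 1.0) for o in onsets]
    times, curves, used, dropped = block_average(_hemo(hbo, events))
    assert used == 2 and dropped == 0
    window = (times >= 0) & (times < 5)
    assert np.allclose(curves[0, window], 1.0)
    # epochs x and -x cancel
    hbo2 = hbo.copy()
    i0 = int(22.0 * FS) - int(2 * FS)
    hbo2[0, i0:i0 + len(template)] = -template
    _, curves2, _, _ = block_average(_hemo(hbo2, events))
    assert np.allclose(curves2, 0.0, atol=1e-12)


def test_partial_epochs_dropped_and_counted():
    hbo = np.zeros((1, int(30 * FS)))
    events = [Event(5.0, 1, 1.0), Event(28.0, 1, 1.0)]  # second runs off the end
    _, _, used, dropped = block_average(_hemo(hbo, events))
    assert used == 1 and dropped == 1
    with pytest.raises(ValueError, match="epochs"):
        block_average(_hemo(hbo, [Event(29.9, 1, 1.0)]))


def test_trial_averaging_suppresses_noise_sqrt_n():
    rng = np.random.default_rng(0)
    n_trials = 32
    n = int((n_trials * 20 + 10) * FS)
    hbo = rng.standard_normal((1, n))
    events = [Event(5.0 + 20 * k, 1, 1.0) for k in range(n_trials)]
    _, curves, used, _ = block_average(_hemo(hbo, events))
    assert used == n_trials
    ratio = hbo.std() / curves.std()
    assert ratio == pytest.approx(np.sqrt(n_trials), rel=0.2)


def test_subject_activation_averages_task_window():
    n = int(40 * FS)
    hbo = np.zeros((1, n))
    onset = 10.0
    i0 = int(onset * FS)
    hbo[0, i0:i0 + int(5 * FS)] = 1.0  # boxcar covering half the 10 s window
    act = subject_activation(_hemo(hbo, [Event(onset, 1, 1.0)]))
    assert act[0] == pytest.approx(0.5, abs=1e-6)
    zero = subject_activation(_hemo(np.zeros((1, n)), [Event(onset, 1, 1.0)]))
    assert zero[0] == 0.0


# ---------------------------------------------------------------- behavior

def test_behavioral_summary_accuracy_and_rt():
    n = 32
    correct = np.ones(n, dtype=bool)
    correct[:2] = False
    log = TrialLog(
        position=np.ones(n, dtype=int),
        response=np.where(correct, 1.0, 2.0),
        rt_ms=np.full(n, 800.0),
        correct=correct,
    )
    acc, rt = behavioral_summary(log)
    assert acc == pytest.approx(30 / 32)
    assert rt == pytest.approx(800.0)


def test_behavioral_summary_with_no_correct_trials_flags_rt_missing():
    log = TrialLog(
        position=[1, 2], response=[2.0, 1.0], rt_ms=[500.0, 700.0],
        correct=[False, False],
    )
    acc, rt = behavioral_summary(log)
    assert acc == 0.0 and np.isnan(rt)
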