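"""Raw-intensity -> hemodynamics preprocessing chain.

The chain follows standard continuous-wave fNIRS practice, in this fixed
order:

1. intensity -> optical-density change, ``OD(t) = -ln(I(t) / mean(I))``;
2. motion-artifact detection (moving amplitude / moving std criteria) and
   spline-based correction of the flagged segments;
3. zero-phase Butterworth band-pass (default 0.01-0.1 Hz) suppressing
   cardiac (1-1.5 Hz), respiratory (0.2-0.5 Hz) and, partially, Mayer-wave
   (~0.1 Hz) physiology;
4. the modified Beer-Lambert inversion to (dHbO, dHbR) with DPF 6.0 and
   3 cm source-detector separation;
5. per-channel z-scoring.

Only dHbO feeds the connectivity and statistics stages; dHbR is retained in
outputs.  All concentration outputs are relative (arbitrary-scaled): the
extinction-coefficient table fixes the scale, and z-scoring removes it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d

from .recording import Event, RawRecording, TrialLog

__all__ = [
    "OpticalDensitySeries",
    "HemoTimeSeries",
    "MbllCoefficients",
    "intensity_to_od",
    "detect_motion",
    "spline_correct",
    "bandpass",
    "mbll",
    "zscore",
    "block_average",
    "subject_activation",
    "behavioral_summary",
    "preprocess_recording",
]


@dataclass
class OpticalDensitySeries:
    """Optical-density change per channel and wavelength (unitless)."""

    od: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    fs: float
    channels: list[str]
    wavelengths_nm: tuple[float, ...]
    events: list[Event] = field(default_factory=list)


@dataclass
class HemoTimeSeries:
    """Relative hemoglobin concentration changes per channel.

    ``hbo``/``hbr`` have shape (n_channels, n_samples).  ``zscored`` flags
    whether per-channel standardization has been applied.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channels: list[str]
    zscored: bool = False
    events: list[Event] = field(default_factory=list)


def _load_extinction_table() -> dict[float, tuple[float, float]]:
    text = (
        resources.files("nirsnet.data")
        .joinpath("extinction_coefficients.tsv")
        .read_text(encoding="utf-8")
    )
    out: dict[float, tuple[float, float]] = {}
    for r in csv.DictReader(
        (ln for ln in text.splitlines() if not ln.startswith("#")), delimiter="\t"
    ):
        out[float(r["wavelength_nm"])] = (float(r["eps_hbo"]), float(r["eps_hbr"]))
    return out


@dataclass(frozen=True)
class MbllCoefficients:
    """Coefficients of the modified Beer-Lambert inversion.

    ``extinction`` maps each wavelength (nm) to (eps_HbO, eps_HbR) in
    1/(M*cm) on the natural-log scale; ``dpf`` is the differential
    path-length factor per wavelength (default 6.0 at both wavelengths);
    ``separation_cm`` is the source-detector distance SD.
    """

    wavelengths_nm: tuple[float, float] = (690.0, 830.0)
    extinction: dict[float, tuple[float, float]] = field(
        default_factory=_load_extinction_table
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    separation_cm: float = 3.0

    def matrix(self) -> np.ndarray:
        """The 2x2 system matrix M with rows [eps_HbO(l)*DPF(l), eps_HbR(l)*DPF(l)]."""
        rows = []
        for wl, d in zip(self.wavelengths_nm, self.dpf):
            if wl not in self.extinction:
                raise ValueError(f"no extinction coefficients for {wl} nm")
            e_hbo, e_hbr = self.extinction[wl]
            rows.append([e_hbo * d, e_hbr * d])
        m = np.asarray(rows)
        if self.separation_cm <= 0:
            raise ValueError("separation must be positive")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise np.linalg.LinAlgError(
                f"Beer-Lambert coefficient matrix is singular: {m.tolist()}"
            )
        return m


def intensity_to_od(rec: RawRecording) -> OpticalDensitySeries:
    """Convert intensities to optical-density changes.

    ``OD(t) = -ln(I(t) / mean(I))`` per (channel, wavelength) series; the
    within-series mean is the reference, so a constant series maps to zero
    OD and uniform rescaling of the intensities leaves OD unchanged.
    """
    rec.validate()
    mean = rec.intensity.mean(axis=2, keepdims=True)
    od = -np.log(rec.intensity / mean)
    return OpticalDensitySeries(
        od=od,
        fs=rec.fs,
        channels=list(rec.channels),
        wavelengths_nm=tuple(rec.wavelengths_nm),
        events=list(rec.events),
    )


def detect_motion(
    od: OpticalDensitySeries,
    window_s: float = 1.0,
    amp_threshold: float = 0.5,
    std_threshold: float = 5.0,
) -> np.ndarray:
    """Flag motion-contaminated samples per channel.

    A sample is flagged when, within a moving window of ``window_s``
    seconds, either the peak-to-peak OD excursion exceeds ``amp_threshold``
    or the moving standard deviation exceeds ``std_threshold`` times the
    channel's median moving std.  The mask is dilated by one window and
    shared across wavelengths.

    Returns a boolean array (n_channels, n_samples).
    """
    if amp_threshold <= 0 or std_threshold <= 0:
        raise ValueError("motion-detection thresholds must be positive")
    n_ch, n_wl, n_t = od.od.shape
    win = max(3, int(round(window_s * od.fs)))
    if win >= n_t:
        raise ValueError("detection window must be shorter than the series")
    mask = np.zeros((n_ch, n_t), dtype=bool)
    for c in range(n_ch):
        for w in range(n_wl):
            x = od.od[c, w]
            ptp = maximum_filter1d(x, win) - minimum_filter1d(x, win)
            # moving std via moving moments
            kern = np.ones(win) / win
            m1 = np.convolve(x, kern, mode="same")
            m2 = np.convolve(x * x, kern, mode="same")
            mstd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
            med = np.median(mstd)
            hit = ptp > amp_threshold
            if med > 0:
                hit |= mstd > std_threshold * med
            mask[c] |= hit
    return binary_dilation(mask, structure=np.ones((1, win), dtype=bool))


def _segments(mask_row: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_row.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))  # half-open [start, stop)


def spline_correct(
    od: OpticalDensitySeries,
    mask: np.ndarray,
    smoothing_p: float = 0.99,
) -> OpticalDensitySeries:
    """Correct flagged motion segments with a smoothing-spline fit.

    Within each contiguous flagged segment the spline trend is subtracted
    and the residual is re-anchored to the preceding clean baseline level;
    any remaining level offset at the segment end (a step artifact) is
    propagated to the following samples so the signal is continuous across
    the correction.  With an empty mask the input is returned unchanged.
    """
    if not (0.0 < smoothing_p < 1.0):
        raise ValueError("smoothing parameter must lie in (0, 1)")
    if mask.shape != (od.od.shape[0], od.od.shape[2]):
        raise ValueError("mask shape must be (n_channels, n_samples)")
    if not mask.any():
        return od
    if mask.all():
        warnings.warn("motion mask covers the entire series; returning input unchanged")
        return od
    out = od.od.copy()
    fs = od.fs
    anchor_win = max(1, int(round(0.5 * fs)))
    lam = (1.0 - smoothing_p) / smoothing_p
    for c in range(out.shape[0]):
        for w in range(out.shape[1]):
            x = out[c, w]
            for start, stop in _segments(mask[c]):
                seg = x[start:stop].copy()
                t = np.arange(start, stop) / fs
                if len(seg) >= 4:
                    spl = make_smoothing_spline(t, seg, lam=lam)
                    trend = spl(t)
                else:
                    trend = np.full_like(seg, seg.mean())
                resid = seg - trend
                if start > 0:
                    base = x[max(0, start - anchor_win):start].mean()
                else:
                    base = x[stop:stop + anchor_win].mean()
                corrected = resid + base
                end_shift = corrected[-anchor_win:].mean() - seg[-anchor_win:].mean()
                x[start:stop] = corrected
                x[stop:] += end_shift
            out[c, w] = x
    return replace(od, od=out)


def bandpass(
    od: OpticalDensitySeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 3,
) -> OpticalDensitySeries:
    """Zero-phase Butterworth band-pass of the OD series.

    Defaults pass 0.01-0.1 Hz: the hemodynamic band of a slow blocked task,
    rejecting DC drift and cardiac/respiratory physiology.  Applied
    forward-backward (``sosfiltfilt``) so the passband has no phase
    distortion.
    """
    nyq = od.fs / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist; got "
            f"({low_hz}, {high_hz}) at fs={od.fs}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=od.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, od.od, axis=2)
    return replace(od, od=filtered)


def mbll(od: OpticalDensitySeries, coef: MbllCoefficients | None = None) -> HemoTimeSeries:
    """Invert the modified Beer-Lambert law.

    Per sample and channel solves
    ``[dHbO, dHbR] = (1/SD) * M^-1 [dA(l1), dA(l2)]`` where row i of M is
    ``[eps_HbO(l_i)*DPF(l_i), eps_HbR(l_i)*DPF(l_i)]``.
    """
    if coef is None:
        coef = MbllCoefficients(wavelengths_nm=tuple(od.wavelengths_nm))
    if tuple(coef.wavelengths_nm) != tuple(od.wavelengths_nm):
        raise ValueError("coefficient wavelengths do not match the OD series")
    m_inv = np.linalg.inv(coef.matrix()) / coef.separation_cm
    conc = np.einsum("ij,cjt->cit", m_inv, od.od)
    return HemoTimeSeries(
        hbo=conc[:, 0, :],
        hbr=conc[:, 1, :],
        fs=od.fs,
        channels=list(od.channels),
        zscored=False,
        events=list(od.events),
    )


def zscore(h: HemoTimeSeries) -> HemoTimeSeries:
    """Standardize each channel to zero mean, unit variance."""
    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=1, keepdims=True)
        flat = np.flatnonzero(sd.ravel() == 0)
        if flat.size:
            raise ValueError(
                f"cannot z-score constant channel {h.channels[flat[0]]}"
            )
        return (x - x.mean(axis=1, keepdims=True)) / sd

    return HemoTimeSeries(
        hbo=_z(h.hbo),
        hbr=_z(h.hbr),
        fs=h.fs,
        channels=list(h.channels),
        zscored=True,
        events=list(h.events),
    )


def block_average(
    h: HemoTimeSeries,
    events: list[Event] | None = None,
    window_s: tuple[float, float] = (-2.0, 15.0),
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Trial-averaged dHbO response per channel.

    Epochs are cut around each event onset over ``window_s`` seconds,
    baseline-corrected by the mean over the pre-onset part of the window,
    and averaged.  Epochs extending past the recording edges are dropped.

    Returns ``(times, curves, n_used, n_dropped)`` with ``curves`` of shape
    (n_channels, n_window_samples).
    """
    if events is None:
        events = h.events
    pre, post = window_s
    if post <= pre:
        raise ValueError("epoch window must have positive length")
    n_t = h.hbo.shape[1]
    i_pre = int(round(pre * h.fs))
    i_post = int(round(post * h.fs))
    length = i_post - i_pre
    epochs = []
    dropped = 0
    for ev in events:
        i0 = int(round(ev.onset_s * h.fs))
        lo, hi = i0 + i_pre, i0 + i_post
        if lo < 0 or hi > n_t:
            dropped += 1
            continue
        ep = h.hbo[:, lo:hi]
        n_base = max(1, -i_pre)
        baseline = ep[:, :n_base].mean(axis=1, keepdims=True) if i_pre < 0 else 0.0
        epochs.append(ep - baseline)
    if not epochs:
        raise ValueError("no usable epochs inside the recording")
    curves = np.mean(epochs, axis=0)
    times = (np.arange(length) + i_pre) / h.fs
    return times, curves, len(epochs), dropped


def subject_activation(
    h: HemoTimeSeries,
    events: list[Event] | None = None,
    task_window_s: tuple[float, float] = (0.0, 10.0),
    baseline_window_s: tuple[float, float] = (-2.0, 15.0),
    mode: str = "mean",
) -> np.ndarray:
    """Per-channel activation scalar entering the group comparison.

    The trial-averaged, baseline-corrected response curve is reduced over
    the task window (0-10 s, the response deadline) to one number per
    channel — its mean by default, its peak with ``mode="peak"``.
    """
    times, curves, _, _ = block_average(h, events, baseline_window_s)
    sel = (times >= task_window_s[0]) & (times < task_window_s[1])
    if not sel.any():
        raise ValueError("task window outside the epoch window")
    if mode == "mean":
        return curves[:, sel].mean(axis=1)
    if mode == "peak":
        return curves[:, sel].max(axis=1)
    raise ValueError(f"unknown activation mode {mode!r}")


def behavioral_summary(log: TrialLog) -> tuple[float, float]:
    """Accuracy and mean reaction time of one subject.

    Accuracy is #correct / #trials; the RT summary is the mean over correct
    trials only (NaN when no trial was correct).
    """
    log.validate()
    accuracy = float(log.correct.mean())
    if log.correct.any():
        rt = float(np.nanmean(log.rt_ms[log.correct]))
    else:
        rt = float("nan")
    return accuracy, rt


def preprocess_recording(
    rec: RawRecording,
    coef: MbllCoefficients | None = None,
    motion_window_s: float = 1.0,
    motion_amp_threshold: float = 0.5,
    motion_std_threshold: float = 5.0,
    spline_smoothing: float = 0.99,
    band_hz: tuple[float, float] | None = (0.01, 0.1),
    do_zscore: bool = True,
    correct_motion: bool = True,
) -> HemoTimeSeries:
    """Run the full chain in its fixed order.

    OD conversion -> motion detection + spline correction -> band-pass ->
    Beer-Lambert inversion -> z-scoring.  Stages can be disabled
    (``band_hz=None``, ``do_zscore=False``, ``correct_motion=False``) but
    never reordered.
    """
    od = intensity_to_od(rec)
    if correct_motion:
        mask = detect_motion(
            od, motion_window_s, motion_amp_threshold, motion_std_threshold
        )
        od = spline_correct(od, mask, spline_smoothing)
    if band_hz is not None:
        od = bandpass(od, band_hz[0], band_hz[1])
    h = mbll(od, coef)
    if do_zscore:
        h = zscore(h)
    return h
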