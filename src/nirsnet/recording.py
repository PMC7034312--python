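"""Raw-recording and trial-log containers with SNIRF and CSV readers/writers.

A :class:`RawRecording` holds strictly positive detector intensities for
every (channel, wavelength) pair at a fixed sampling rate, plus task event
markers.  Two on-disk formats are supported:

* SNIRF — the community HDF5 standard for NIRS, written/read directly with
  h5py (``/nirs/data1`` time series, per-column measurement lists,
  ``/nirs/probe`` geometry, ``/nirs/stim1`` events).
* CSV — a dependency-light long format ``time_s,channel,wavelength_nm,
  intensity`` with events in a sibling ``*.events.csv`` file; trivially
  diffable and byte-stable under write -> read -> write.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .montage import ProbeMontage, builtin_montage

__all__ = [
    "RawRecording",
    "TrialLog",
    "Event",
    "load_recording",
    "write_recording",
    "load_trial_log",
    "write_trial_log",
]


@dataclass(frozen=True)
class Event:
    """Task event marker: onset (s), integer code, duration (s)."""

    onset_s: float
    code: int
    duration_s: float


@dataclass
class RawRecording:
    """Per-channel, per-wavelength raw intensity time series.

    Attributes
    ----------
    subject_id : str
    group : str
        Group label, e.g. ``"DS"`` or ``"TD"``.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel names in fixed montage order.
    wavelengths_nm : tuple of float
    intensity : ndarray, shape (n_channels, n_wavelengths, n_samples)
        Detector intensities in arbitrary units; strictly positive.
    events : list of Event
    """

    subject_id: str
    group: str
    fs: float
    channels: list[str]
    wavelengths_nm: tuple[float, ...]
    intensity: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("recording has no channels")
        if self.intensity.ndim != 3 or self.intensity.shape[:2] != (
            len(self.channels),
            len(self.wavelengths_nm),
        ):
            raise ValueError(
                "intensity must have shape (n_channels, n_wavelengths, n_samples); "
                f"got {self.intensity.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(self.intensity > 0):
            bad = np.argwhere(self.intensity <= 0)[0]
            raise ValueError(
                "intensity must be strictly positive; first offending sample at "
                f"channel={self.channels[bad[0]]}, wavelength="
                f"{self.wavelengths_nm[bad[1]]} nm, index={bad[2]}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def __eq__(self, other) -> bool:  # sample-exact equality
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.fs == other.fs
            and self.channels == other.channels
            and tuple(self.wavelengths_nm) == tuple(other.wavelengths_nm)
            and self.intensity.shape == other.intensity.shape
            and np.array_equal(self.intensity, other.intensity)
            and self.events == other.events
        )


@dataclass
class TrialLog:
    """Behavioral log of one subject's run.

    Each trial records the stimulus position (1-4), the key pressed (1-4, or
    ``None`` for a miss), the reaction time in ms, and whether the response
    was correct (response key equals stimulus position).
    """

    position: np.ndarray
    response: np.ndarray  # float array; NaN marks a missing response
    rt_ms: np.ndarray  # NaN when no response
    correct: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=int)
        self.response = np.asarray(self.response, dtype=float)
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.position)
        if not (len(self.response) == len(self.rt_ms) == len(self.correct) == n):
            raise ValueError("trial-log columns differ in length")
        if n == 0:
            raise ValueError("trial log is empty")
        if not np.all(np.isin(self.position, [1, 2, 3, 4])):
            raise ValueError("stimulus positions must be in {1, 2, 3, 4}")
        answered = ~np.isnan(self.response)
        if not np.all(np.isin(self.response[answered], [1, 2, 3, 4])):
            raise ValueError("response keys must be in {1, 2, 3, 4}")
        rt = self.rt_ms[answered]
        if np.any(np.isnan(rt)) or np.any(rt <= 0) or np.any(rt > 10_000):
            raise ValueError("reaction times must lie in (0, 10000] ms")
        expected = answered & (self.response == self.position)
        if not np.array_equal(expected, self.correct):
            raise ValueError("correct flags inconsistent with responses")

    @property
    def n_trials(self) -> int:
        return len(self.position)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "position": self.position,
                "response": self.response,
                "rt_ms": self.rt_ms,
                "correct": self.correct.astype(int),
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialLog):
            return NotImplemented
        eq = np.array_equal
        return (
            eq(self.position, other.position)
            and eq(self.response, other.response, equal_nan=True)
            and eq(self.rt_ms, other.rt_ms, equal_nan=True)
            and eq(self.correct, other.correct)
        )


# --------------------------------------------------------------------------
# CSV format
# --------------------------------------------------------------------------

def _events_path(path: str) -> str:
    root, _ = os.path.splitext(path)
    return root + ".events.csv"


def _write_csv(rec: RawRecording, path: str) -> None:
    n_ch, n_wl, n_t = rec.intensity.shape
    times = rec.times
    buf = io.StringIO()
    buf.write(f"# subject={rec.subject_id}\n")
    buf.write(f"# group={rec.group}\n")
    buf.write(f"# fs_hz={rec.fs!r}\n")
    buf.write("time_s,channel,wavelength_nm,intensity\n")
    time_strs = [repr(float(t)) for t in times]
    for c in range(n_ch):
        for w in range(n_wl):
            ch = rec.channels[c]
            wl = repr(float(rec.wavelengths_nm[w]))
            col = rec.intensity[c, w]
            for t in range(n_t):
                buf.write(f"{time_strs[t]},{ch},{wl},{float(col[t])!r}\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    ev = pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in rec.events],
            "code": [e.code for e in rec.events],
            "duration_s": [e.duration_s for e in rec.events],
        }
    )
    with open(_events_path(path), "w", encoding="utf-8", newline="") as fh:
        fh.write("onset_s,code,duration_s\n")
        for e in rec.events:
            fh.write(f"{float(e.onset_s)!r},{e.code},{float(e.duration_s)!r}\n")
    del ev


def _read_csv(path: str) -> RawRecording:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"malformed recording CSV {path}: {exc}") from None
    required = {"time_s", "channel", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"malformed recording CSV {path}: missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    channels = list(dict.fromkeys(df["channel"]))
    wavelengths = tuple(sorted(df["wavelength_nm"].unique()))
    n_t = df["time_s"].nunique()
    intensity = np.empty((len(channels), len(wavelengths), n_t))
    counts = set()
    for c, ch in enumerate(channels):
        for w, wl in enumerate(wavelengths):
            series = df[(df["channel"] == ch) & (df["wavelength_nm"] == wl)]
            counts.add(len(series))
            if len(series) != n_t:
                raise ValueError(
                    f"malformed recording CSV {path}: channel {ch} at {wl} nm has "
                    f"{len(series)} samples, expected {n_t}"
                )
            intensity[c, w] = series["intensity"].to_numpy()
    fs = float(meta.get("fs_hz", "nan"))
    if not np.isfinite(fs):
        t = np.sort(df["time_s"].unique())
        fs = 1.0 / (t[1] - t[0])
    events: list[Event] = []
    ep = _events_path(path)
    if os.path.exists(ep):
        ev = pd.read_csv(ep, float_precision="round_trip")
        events = [
            Event(float(r.onset_s), int(r.code), float(r.duration_s))
            for r in ev.itertuples()
        ]
    return RawRecording(
        subject_id=meta.get("subject", "unknown"),
        group=meta.get("group", "unknown"),
        fs=fs,
        channels=channels,
        wavelengths_nm=wavelengths,
        intensity=intensity,
        events=events,
    )


# --------------------------------------------------------------------------
# SNIRF format (HDF5)
# --------------------------------------------------------------------------

def _write_snirf(rec: RawRecording, path: str, montage: ProbeMontage | None) -> None:
    if montage is None:
        montage, _ = builtin_montage()
    n_ch, n_wl, n_t = rec.intensity.shape
    str_t = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=str_t)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id, dtype=str_t)
        meta.create_dataset("MeasurementDate", data="unknown", dtype=str_t)
        meta.create_dataset("MeasurementTime", data="unknown", dtype=str_t)
        meta.create_dataset("LengthUnit", data="mm", dtype=str_t)
        meta.create_dataset("TimeUnit", data="s", dtype=str_t)
        meta.create_dataset("FrequencyUnit", data="Hz", dtype=str_t)
        meta.create_dataset("Group", data=rec.group, dtype=str_t)
        meta.create_dataset("SamplingFrequency", data=float(rec.fs))

        data = nirs.create_group("data1")
        ts = rec.intensity.reshape(n_ch * n_wl, n_t).T  # columns: ch-major, wl-minor
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=rec.times)
        src_ids = list(montage.sources)
        det_ids = list(montage.detectors)
        for c in range(n_ch):
            s_id, d_id = montage.channels[c]
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{c * n_wl + w + 1}")
                ml.create_dataset("sourceIndex", data=src_ids.index(s_id) + 1)
                ml.create_dataset("detectorIndex", data=det_ids.index(d_id) + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        probe.create_dataset(
            "sourcePos3D", data=np.array([montage.sources[s] for s in src_ids])
        )
        probe.create_dataset(
            "detectorPos3D", data=np.array([montage.detectors[d] for d in det_ids])
        )
        probe.create_dataset("sourceLabels", data=src_ids, dtype=str_t)
        probe.create_dataset("detectorLabels", data=det_ids, dtype=str_t)

        if rec.events:
            stim = nirs.create_group("stim1")
            stim.create_dataset("name", data="trial", dtype=str_t)
            stim.create_dataset(
                "data",
                data=np.array(
                    [[e.onset_s, e.duration_s, float(e.code)] for e in rec.events]
                ),
            )


def _read_snirf(path: str) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise ValueError(f"malformed SNIRF file {path}: missing /nirs/data1")
        nirs = f["nirs"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        meta = nirs["metaDataTags"]

        def _s(ds) -> str:
            v = ds[()]
            return v.decode() if isinstance(v, bytes) else str(v)

        ml_names = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if ts.ndim != 2 or ts.shape[1] != len(ml_names):
            raise ValueError(
                f"malformed SNIRF file {path}: dataTimeSeries columns do not match "
                "measurementList entries"
            )
        wl = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())
        n_wl = len(wl)
        n_ch = len(ml_names) // n_wl
        src_labels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in nirs["probe"]["sourceLabels"][()]
        ]
        det_labels = [
            d.decode() if isinstance(d, bytes) else str(d)
            for d in nirs["probe"]["detectorLabels"][()]
        ]
        del src_labels, det_labels  # geometry carried by the montage fixture
        channels = [f"CH{i:02d}" for i in range(1, n_ch + 1)]
        intensity = ts.T.reshape(n_ch, n_wl, -1)
        if "SamplingFrequency" in meta:
            fs = float(meta["SamplingFrequency"][()])
        else:
            fs = float((len(time) - 1) / (time[-1] - time[0]))
        events: list[Event] = []
        for k in sorted(k for k in nirs if k.startswith("stim")):
            stim = np.atleast_2d(np.asarray(nirs[k]["data"]))
            for onset, dur, code in stim:
                events.append(Event(float(onset), int(code), float(dur)))
        return RawRecording(
            subject_id=_s(meta["SubjectID"]),
            group=_s(meta["Group"]) if "Group" in meta else "unknown",
            fs=fs,
            channels=channels,
            wavelengths_nm=wl,
            intensity=intensity,
            events=events,
        )


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------

def write_recording(
    rec: RawRecording,
    path: str,
    format: str = "snirf",
    montage: ProbeMontage | None = None,
) -> str:
    """Write a recording to disk in SNIRF or long-format CSV.

    Returns the path written.  CSV output is byte-stable: writing, reading
    and writing again produces identical bytes.
    """
    rec.validate()
    if format == "csv":
        _write_csv(rec, path)
    elif format == "snirf":
        _write_snirf(rec, path, montage)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'snirf' or 'csv'")
    return path


def load_recording(path: str, format: str | None = None) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    ``format`` defaults from the file extension (``.snirf``/``.h5`` vs
    ``.csv``).  Raises ``ValueError`` for malformed files or invariant
    violations (e.g. non-positive intensity).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "snirf"
    if format == "csv":
        return _read_csv(path)
    if format == "snirf":
        return _read_snirf(path)
    raise ValueError(f"unknown format {format!r}; expected 'snirf' or 'csv'")


def write_trial_log(log: TrialLog, path: str) -> str:
    log.validate()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("trial,position,response,rt_ms,correct\n")
        for i in range(log.n_trials):
            resp = "" if np.isnan(log.response[i]) else str(int(log.response[i]))
            rt = "" if np.isnan(log.rt_ms[i]) else repr(float(log.rt_ms[i]))
            fh.write(
                f"{i + 1},{log.position[i]},{resp},{rt},{int(log.correct[i])}\n"
            )
    return path


def load_trial_log(path: str) -> TrialLog:
    df = pd.read_csv(path, float_precision="round_trip")
    return TrialLog(
        position=df["position"].to_numpy(),
        response=df["response"].to_numpy(dtype=float),
        rt_ms=df["rt_ms"].to_numpy(dtype=float),
        correct=df["correct"].to_numpy(dtype=bool),
    )
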