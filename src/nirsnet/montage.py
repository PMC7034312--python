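"""Probe geometry and channel anatomy for the 13-channel motor/prefrontal montage.

The montage couples a continuous-wave fNIRS head patch (4 laser sources, 8
detectors, nominal 3 cm source-detector separation, 690/830 nm) to anatomical
metadata: one MNI coordinate per channel plus Brodmann-area labels with
registration probabilities.  Anatomy is carried as opaque metadata — nothing
downstream computes with the coordinates; they fix channel identity and
ordering (CH01..CH13) for every matrix produced by the pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ProbeMontage",
    "ChannelAnnotation",
    "builtin_montage",
    "N_CHANNELS",
    "CHANNEL_NAMES",
]

N_CHANNELS = 13
CHANNEL_NAMES = tuple(f"CH{i:02d}" for i in range(1, N_CHANNELS + 1))

# Synthetic planar optode layout (mm).  The study montage's true 3D optode
# positions were digitizer-measured and are not part of the public record;
# these coordinates only encode which source pairs with which detector, with
# a nominal 30 mm pitch.  Channel anatomy comes from the table fixture.
_SOURCE_POS = {
    "S1": (15.0, 0.0, 0.0),
    "S2": (45.0, 30.0, 0.0),
    "S3": (75.0, 0.0, 0.0),
    "S4": (105.0, 30.0, 0.0),
}
_DETECTOR_POS = {
    "D1": (0.0, 30.0, 0.0),
    "D2": (30.0, 30.0, 0.0),
    "D3": (0.0, -15.0, 0.0),
    "D4": (30.0, -15.0, 0.0),
    "D5": (60.0, 30.0, 0.0),
    "D6": (60.0, -15.0, 0.0),
    "D7": (90.0, 30.0, 0.0),
    "D8": (120.0, -15.0, 0.0),
}
_CHANNEL_PAIRS = (
    ("S1", "D1"), ("S1", "D2"), ("S1", "D3"), ("S1", "D4"),
    ("S2", "D2"), ("S2", "D5"), ("S2", "D4"),
    ("S3", "D5"), ("S3", "D6"), ("S3", "D7"),
    ("S4", "D7"), ("S4", "D8"), ("S4", "D5"),
)


@dataclass(frozen=True)
class ProbeMontage:
    """Optode layout of a CW fNIRS patch.

    Attributes
    ----------
    sources, detectors : dict
        Optode id -> 3D position in mm.
    channels : tuple of (source id, detector id)
        Ordered channel list; index i is channel ``CH{i+1:02d}`` everywhere
        downstream (correlation matrices, plots, result tables).
    separation_cm : float
        Nominal source-detector separation in cm (the SD term of the
        Beer-Lambert inversion).
    wavelengths_nm : tuple of float
        The two laser wavelengths in nm.
    """

    sources: dict[str, tuple[float, float, float]]
    detectors: dict[str, tuple[float, float, float]]
    channels: tuple[tuple[str, str], ...]
    separation_cm: float = 3.0
    wavelengths_nm: tuple[float, float] = (690.0, 830.0)

    def __post_init__(self) -> None:
        if self.separation_cm <= 0:
            raise ValueError("source-detector separation must be positive")
        w1, w2 = self.wavelengths_nm
        if w1 <= 0 or w2 <= 0 or w1 == w2:
            raise ValueError("wavelengths must be distinct and positive")
        for s, d in self.channels:
            if s not in self.sources:
                raise ValueError(f"channel references unknown source {s!r}")
            if d not in self.detectors:
                raise ValueError(f"channel references unknown detector {d!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"CH{i:02d}" for i in range(1, len(self.channels) + 1))


@dataclass(frozen=True)
class ChannelAnnotation:
    """Anatomical annotation of one channel: MNI coordinate plus candidate
    Brodmann areas with registration probabilities in (0, 1]."""

    channel: str
    mni: tuple[float, float, float]
    areas: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        total = 0.0
        for label, p in self.areas:
            if not (0.0 < p <= 1.0):
                raise ValueError(
                    f"{self.channel}: probability {p} for {label!r} outside (0, 1]"
                )
            total += p
        if total > 1.0 + 0.01:
            raise ValueError(f"{self.channel}: probabilities sum to {total:.3f} > 1")


def _load_channel_table() -> list[ChannelAnnotation]:
    text = (
        resources.files("nirsnet.data")
        .joinpath("montage_channels.tsv")
        .read_text(encoding="utf-8")
    )
    rows = [
        r
        for r in csv.DictReader(
            (ln for ln in text.splitlines() if not ln.startswith("#")),
            delimiter="\t",
        )
    ]
    by_channel: dict[str, dict] = {}
    for r in rows:
        entry = by_channel.setdefault(
            r["channel"],
            {"mni": (float(r["mni_x"]), float(r["mni_y"]), float(r["mni_z"])), "areas": []},
        )
        entry["areas"].append((r["brodmann_label"], float(r["probability"])))
    return [
        ChannelAnnotation(ch, by_channel[ch]["mni"], tuple(by_channel[ch]["areas"]))
        for ch in sorted(by_channel)
    ]


def builtin_montage() -> tuple[ProbeMontage, list[ChannelAnnotation]]:
    """Return the built-in 13-channel left motor/prefrontal montage.

    Returns the probe layout (4 sources x 8 detectors pairing into 13
    channels, 3 cm separation, 690/830 nm) together with the per-channel
    anatomical table: MNI coordinates and Brodmann-area probabilities,
    reproduced exactly from the shipped fixture.
    """
    montage = ProbeMontage(
        sources=dict(_SOURCE_POS),
        detectors=dict(_DETECTOR_POS),
        channels=_CHANNEL_PAIRS,
    )
    annotations = _load_channel_table()
    if len(annotations) != N_CHANNELS:
        raise RuntimeError("channel table fixture is corrupt")
    return montage, annotations
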