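"""Two-group synthetic fNIRS generator.

Emulates a blocked fine-motor task acquisition: 32 trials, 500 ms fixation,
a response window of at most 10 s, and a 15 s inter-trial baseline, sampled
at 50 Hz over 13 channels at 690/830 nm.  Each subject's latent dHbO is the
sum of

* an HRF-convolved task response (double-gamma HRF, per-channel amplitude
  with a group-dependent profile and a per-subject gain),
* slow band-limited "network" fluctuations with a controlled correlation
  structure: a spatially banded coupling over the CH01..CH13 ordering
  (neighbors within distance 4 couple, strength decaying with distance),
  randomized Watts-Strogatz style — each beyond-nearest-neighbor coupling
  relocates to a random channel pair with the group's rewiring
  probability, the nearest-neighbor chain always remaining in place so
  graphs stay connected.  A low rewiring probability (TD-like) yields
  clustered lattice-like thresholded graphs with long paths; a high one
  (DS-like) converts local structure into long-range shortcuts — more
  random graphs with shorter paths and higher global efficiency,
* sinusoidal physiology at cardiac (1-1.5 Hz), respiratory (0.2-0.5 Hz) and
  Mayer-wave (~0.1 Hz) frequencies, plus white noise,
* optional step/spike motion artifacts (exponential inter-arrival times).

Latent (dHbO, dHbR) is pushed through the forward Beer-Lambert model to
two-wavelength intensities, so the preprocessing chain can invert it.
Behavioral logs draw log-normal reaction times and Bernoulli accuracy; in
the typically-developing profile the per-subject accuracy is coupled to the
subject's pre-motor (CH08) gain, giving a recoverable brain-behavior
correlation.

Group defaults target the study conditions being emulated: 7 "DS"-like and
6 "TD"-like subjects; DS reaction times near 3562 ms and accuracy near
0.86 with reduced activation on channels 1, 8 and 9 and a more random
topology; TD reaction times near 1202 ms, accuracy near 0.958, modular
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import CHANNEL_NAMES, N_CHANNELS
from .preprocess import MbllCoefficients
from .recording import Event, RawRecording, TrialLog

__all__ = [
    "GroupParams",
    "SimulationConfig",
    "default_config",
    "simulate_subject",
    "simulate_group_dataset",
    "latent_connectivity",
]


def double_gamma_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, peak_s) - gamma_dist.pdf(t, undershoot_s) / ratio
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass(frozen=True)
class GroupParams:
    """Group-level generator profile."""

    activation_um: tuple[float, ...]  # per-channel dHbO response peak, micromolar
    rt_mean_ms: float  # between-subject mean RT
    rt_sd_ms: float  # between-subject SD of subject-mean RT
    rt_trial_cv: float  # within-subject trial-to-trial coefficient of variation
    accuracy: float  # per-trial probability of a correct response
    rewire_prob: float  # probability a non-chain latent coupling is relocated
    accuracy_coupling: float = 0.0  # d(accuracy)/d(CH08 gain - 1)

    def validate(self) -> None:
        if any(a < 0 for a in self.activation_um):
            raise ValueError("activation amplitudes must be nonnegative")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if not (0.0 <= self.rewire_prob <= 1.0):
            raise ValueError("rewiring probability must lie in [0, 1]")
        if self.rt_mean_ms <= 0 or self.rt_sd_ms < 0 or self.rt_trial_cv < 0:
            raise ValueError("reaction-time parameters must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generator configuration; identical seed + config => identical data."""

    seed: int = 0
    n_per_group: dict[str, int] = field(default_factory=lambda: {"DS": 7, "TD": 6})
    groups: dict[str, GroupParams] = field(default_factory=dict)
    fs: float = 50.0
    n_trials: int = 32
    fixation_ms: float = 500.0
    response_deadline_ms: float = 10_000.0
    iti_s: float = 15.0
    lead_in_s: float = 5.0
    # HRF shape
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 6.0
    # noise amplitudes (micromolar dHbO equivalents)
    network_amp_um: float = 0.8
    within_corr: float = 0.8
    communities: tuple[int, ...] = (0,) * 6 + (1,) * 7  # CH01-06 vs CH07-13
    cardiac_amp_um: float = 0.2
    cardiac_band_hz: tuple[float, float] = (1.0, 1.5)
    resp_amp_um: float = 0.1
    resp_band_hz: tuple[float, float] = (0.2, 0.5)
    mayer_amp_um: float = 0.3
    mayer_band_hz: tuple[float, float] = (0.08, 0.12)
    white_amp_um: float = 0.05
    # motion artifacts
    motion_rate_per_min: float = 0.0
    motion_amp_od: float = 0.3
    # subject-level variability
    subject_gain_sd: float = 0.15  # log-normal sigma of the per-subject gain
    channel_gain_sd: float = 0.05
    hbr_ratio: float = -0.3  # dHbR = hbr_ratio * dHbO

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(
                    f"group {g!r} has {n} subjects; at least 2 are required for "
                    "group statistics"
                )
            if g not in self.groups:
                raise ValueError(f"no generator profile for group {g!r}")
        for gp in self.groups.values():
            gp.validate()
        if self.fs <= 0 or self.n_trials < 1:
            raise ValueError("sampling rate and trial count must be positive")
        for amp in (
            self.network_amp_um, self.cardiac_amp_um, self.resp_amp_um,
            self.mayer_amp_um, self.white_amp_um, self.motion_rate_per_min,
            self.motion_amp_od,
        ):
            if amp < 0:
                raise ValueError("noise amplitudes and rates must be nonnegative")
        if not (0.0 <= self.within_corr <= 1.0):
            raise ValueError("within-community correlation must lie in [0, 1]")
        if len(self.communities) != N_CHANNELS:
            raise ValueError("community assignment must cover all 13 channels")
        # physiology must be resolvable at the configured rate
        fmax = max(self.cardiac_band_hz[1], self.resp_band_hz[1], self.mayer_band_hz[1])
        if self.fs <= 2 * fmax:
            raise ValueError("sampling rate must exceed twice the highest noise frequency")


_DS_AMPLITUDE = tuple(0.1 if i in (0, 7, 8) else 1.0 for i in range(N_CHANNELS))
_TD_AMPLITUDE = (1.0,) * N_CHANNELS


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default two-group configuration emulating the study conditions.

    DS-like: reduced response on channels 1, 8, 9 (frontopolar/pre-motor/
    supplementary-motor), slow inaccurate behavior, rewired (more random)
    topology.  TD-like: full response, fast accurate behavior, modular
    topology with accuracy coupled to the CH08 gain.
    """
    groups = {
        "DS": GroupParams(
            activation_um=_DS_AMPLITUDE,
            rt_mean_ms=3562.1,
            rt_sd_ms=1285.0,  # 485.7 * sqrt(7): SEM -> between-subject SD
            rt_trial_cv=0.25,
            accuracy=0.86,
            rewire_prob=0.65,
        ),
        "TD": GroupParams(
            activation_um=_TD_AMPLITUDE,
            rt_mean_ms=1202.4,
            rt_sd_ms=294.4,  # 120.2 * sqrt(6)
            rt_trial_cv=0.25,
            accuracy=0.958,
            rewire_prob=0.05,
            accuracy_coupling=0.3,
        ),
    }
    return replace(SimulationConfig(seed=seed, groups=groups), **overrides)


def _subject_rng(cfg: SimulationConfig, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_seed]))


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (Hz)."""
    x = rng.standard_normal(n)
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _latent_rng(cfg: SimulationConfig, subject_seed: int) -> np.random.Generator:
    # independent stream so the coupling structure can be reproduced
    # without replaying the subject's full draw sequence
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_seed, 1]))


def _nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to a valid correlation matrix."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < 1e-3:
        vals = np.clip(vals, 1e-3, None)
        r = vecs @ np.diag(vals) @ vecs.T
        d = 1.0 / np.sqrt(np.diag(r))
        r = d[:, None] * r * d[None, :]
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
    return r


def latent_connectivity(
    cfg: SimulationConfig, group: str, subject_seed: int = 0
) -> np.ndarray:
    """Target correlation matrix of the latent slow-fluctuation component.

    The structured couplings form a banded lattice over the CH01..CH13
    ordering: channel pairs at distance d = 1..4 couple with strength
    ``within_corr ** d``.  Each coupling beyond nearest neighbors is
    relocated, with the group's ``rewire_prob``, to a random currently
    uncoupled pair at unchanged strength (Watts-Strogatz rewiring); the
    nearest-neighbor chain is never rewired, keeping every latent graph
    connected.  The assembled matrix is projected to the nearest valid
    correlation matrix.  This per-subject, seed-reproducible structure is
    the pre-noise ground truth that connectivity estimation should
    approach.
    """
    if group not in cfg.groups:
        raise ValueError(f"unknown group label {group!r}")
    gp = cfg.groups[group]
    rng = _latent_rng(cfg, subject_seed)
    n = N_CHANNELS
    w = cfg.within_corr
    strength: dict[tuple[int, int], float] = {}
    for d in (1, 2, 3, 4):
        for i in range(n - d):
            strength[(i, i + d)] = w**d
    for pair in [p for p in strength if p[1] - p[0] >= 2]:
        if rng.random() < gp.rewire_prob:
            free = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if (i, j) not in strength
            ]
            if not free:
                continue
            new = free[rng.integers(0, len(free))]
            strength[new] = strength.pop(pair)
    r = np.eye(n)
    for (i, j), s in strength.items():
        r[i, j] = r[j, i] = s
    return _nearest_correlation(r)


def _behavior(
    cfg: SimulationConfig, gp: GroupParams, rng: np.random.Generator, gain_ch8: float
) -> tuple[TrialLog, np.ndarray]:
    """Draw a trial log; returns (log, response durations in s per trial)."""
    # subject-mean RT: log-normal hitting the group mean/SD
    mu = gp.rt_mean_ms
    sd = gp.rt_sd_ms
    sigma2 = np.log1p((sd / mu) ** 2)
    subj_rt = rng.lognormal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2))
    acc_p = float(np.clip(gp.accuracy + gp.accuracy_coupling * (gain_ch8 - 1.0), 0, 1))
    sig_t2 = np.log1p(gp.rt_trial_cv**2)
    position = rng.integers(1, 5, size=cfg.n_trials)
    rt = rng.lognormal(np.log(subj_rt) - sig_t2 / 2, np.sqrt(sig_t2), size=cfg.n_trials)
    answered = rt <= cfg.response_deadline_ms
    correct_draw = rng.random(cfg.n_trials) < acc_p
    response = np.full(cfg.n_trials, np.nan)
    for i in range(cfg.n_trials):
        if not answered[i]:
            continue
        if correct_draw[i]:
            response[i] = position[i]
        else:
            wrong = [k for k in (1, 2, 3, 4) if k != position[i]]
            response[i] = wrong[rng.integers(0, 3)]
    rt_out = np.where(answered, rt, np.nan)
    correct = answered & (response == position)
    log = TrialLog(position=position, response=response, rt_ms=rt_out, correct=correct)
    durations = np.where(answered, rt, cfg.response_deadline_ms) / 1000.0
    return log, durations


def simulate_subject(
    cfg: SimulationConfig,
    group: str,
    subject_seed: int,
    return_latent: bool = False,
):
    """Generate one subject's raw recording and trial log.

    ``subject_seed`` individualizes the subject under the master seed;
    the pair (config, master seed, subject seed) fully determines the
    output.  With ``return_latent=True`` a third element carries the
    injected ground truth (``hbo_um``, ``hbr_um``, ``latent_corr``,
    ``gain``) for forward-model verification.
    """
    cfg.validate()
    if group not in cfg.groups:
        raise ValueError(f"unknown group label {group!r}")
    gp = cfg.groups[group]
    rng = _subject_rng(cfg, subject_seed)

    # per-subject and per-channel response gains
    gain = float(rng.lognormal(-cfg.subject_gain_sd**2 / 2, cfg.subject_gain_sd))
    ch_gain = rng.lognormal(
        -cfg.channel_gain_sd**2 / 2, cfg.channel_gain_sd, size=N_CHANNELS
    )
    log, durations = _behavior(cfg, gp, rng, gain)

    # task timeline
    onsets = np.empty(cfg.n_trials)
    t = cfg.lead_in_s
    for i in range(cfg.n_trials):
        t += cfg.fixation_ms / 1000.0
        onsets[i] = t
        t += durations[i] + cfg.iti_s
    total_s = t + cfg.lead_in_s
    n = int(round(total_s * cfg.fs))
    times = np.arange(n) / cfg.fs

    # HRF-convolved task regressor, shared across channels
    boxcar = np.zeros(n)
    for onset, dur in zip(onsets, durations):
        i0, i1 = int(round(onset * cfg.fs)), int(round((onset + dur) * cfg.fs))
        boxcar[i0:min(i1, n)] = 1.0
    hrf_t = np.arange(0, 32.0, 1 / cfg.fs)
    hrf = double_gamma_hrf(hrf_t, cfg.hrf_peak_s, cfg.hrf_undershoot_s, cfg.hrf_ratio)
    regressor = np.convolve(boxcar, hrf)[:n]
    peak = regressor.max()
    if peak > 0:
        regressor /= peak

    amps = np.asarray(gp.activation_um) * gain * ch_gain
    hbo = amps[:, None] * regressor[None, :]

    # correlated slow fluctuations realizing the latent correlation target
    if cfg.network_amp_um > 0:
        r_target = latent_connectivity(cfg, group, subject_seed)
        chol = np.linalg.cholesky(r_target)
        base = np.stack(
            [_band_limited_noise(rng, n, cfg.fs, (0.01, 0.1)) for _ in range(N_CHANNELS)]
        )
        hbo += cfg.network_amp_um * (chol @ base)

    # sinusoidal physiology with subject-level frequencies, channel phases
    for amp, band in (
        (cfg.cardiac_amp_um, cfg.cardiac_band_hz),
        (cfg.resp_amp_um, cfg.resp_band_hz),
        (cfg.mayer_amp_um, cfg.mayer_band_hz),
    ):
        if amp <= 0:
            continue
        f = rng.uniform(*band)
        phases = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        hbo += amp * np.sin(2 * np.pi * f * times[None, :] + phases[:, None])
    if cfg.white_amp_um > 0:
        hbo += cfg.white_amp_um * rng.standard_normal((N_CHANNELS, n))

    hbr = cfg.hbr_ratio * hbo

    # forward Beer-Lambert: concentrations (M) -> dA -> intensities
    coef = MbllCoefficients()
    m = coef.matrix()
    conc = np.stack([hbo, hbr], axis=1) * 1e-6  # micromolar -> molar
    d_a = coef.separation_cm * np.einsum("ij,cjt->cit", m, conc)

    # motion artifacts enter the optical domain (both wavelengths alike)
    if cfg.motion_rate_per_min > 0 and cfg.motion_amp_od > 0:
        rate_hz = cfg.motion_rate_per_min / 60.0
        t_ev = rng.exponential(1 / rate_hz)
        while t_ev < total_s:
            i0 = int(round(t_ev * cfg.fs))
            ch = rng.integers(0, N_CHANNELS)
            amp = cfg.motion_amp_od * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
            if rng.random() < 0.5:  # sustained step
                d_a[ch, :, i0:] += amp
            else:  # decaying spike
                tail = times[i0:] - times[i0]
                d_a[ch, :, i0:] += amp * np.exp(-tail / 0.3)
            t_ev += rng.exponential(1 / rate_hz)

    i0_ch = rng.uniform(0.5, 2.0, size=(N_CHANNELS, 2, 1))
    intensity = i0_ch * np.exp(-d_a)

    events = [
        Event(float(o), int(p), float(d))
        for o, p, d in zip(onsets, log.position, durations)
    ]
    rec = RawRecording(
        subject_id=f"{group}{subject_seed:02d}",
        group=group,
        fs=cfg.fs,
        channels=list(CHANNEL_NAMES),
        wavelengths_nm=coef.wavelengths_nm,
        intensity=intensity,
        events=events,
    )
    if return_latent:
        latent = {
            "hbo_um": hbo,
            "hbr_um": hbr,
            "latent_corr": latent_connectivity(cfg, group, subject_seed),
            "gain": gain,
        }
        return rec, log, latent
    return rec, log


def simulate_group_dataset(cfg: SimulationConfig) -> list[tuple[RawRecording, TrialLog]]:
    """Generate the full two-group dataset (defaults: 7 DS-like + 6 TD-like).

    Subject seeds run consecutively within each group so any subject can be
    regenerated standalone with :func:`simulate_subject`.
    """
    cfg.validate()
    out: list[tuple[RawRecording, TrialLog]] = []
    seed_counter = 0
    for group in cfg.n_per_group:
        for _ in range(cfg.n_per_group[group]):
            out.append(simulate_subject(cfg, group, seed_counter))
            seed_counter += 1
    return out
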