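# Methods

This note documents the models, conventions and design choices behind
nirsnet, in the order data flows through the package.

## Acquisition model

The package targets continuous-wave fNIRS recordings of a blocked fine
motor task: 13 channels formed by 4 sources and 8 detectors over the left
motor/prefrontal cortex, 3 cm nominal source–detector separation,
wavelengths 690 and 830 nm, 50 Hz sampling.  The built-in montage carries
each channel's MNI coordinate and Brodmann-area probabilities as opaque
metadata reproduced from the shipped fixture table; no spatial
registration is computed.  The optode 3D coordinates themselves are a
synthetic planar layout (the pairing structure is what matters; real
digitizer coordinates are study-specific).  One printed label assigns
Brodmann area 5 to a premotor/supplementary-motor channel; the fixture
reproduces the table as printed rather than correcting it.

The task structure is 32 trials: 500 ms fixation, a stimulus requiring a
keyed response within 10 s, and a 15 s inter-trial baseline so hemodynamic
responses can return to baseline.

## Preprocessing chain

Order is fixed: OD conversion → motion detection/correction → band-pass →
Beer–Lambert inversion → z-scoring.

- **Optical density.** ΔA(t) = −ln I(t)/Ī with the within-series mean as
  reference, so constant series map to zero and uniform intensity
  rescaling has no effect.
- **Motion artifacts.** A sample is flagged when the peak-to-peak
  excursion within a 1 s moving window exceeds 0.5 OD, or the moving
  standard deviation exceeds 5× the channel's median moving SD; the mask
  is dilated by one window.  Flagged segments are corrected by
  subtracting a fitted smoothing spline (parameter 0.99 on the usual
  (0, 1) smoothing scale) and re-anchoring the residual to the preceding
  clean baseline; any residual level offset at the segment end — the
  signature of a step artifact — is propagated to the following samples so
  the corrected signal is continuous.  Consequence: samples *after* a
  corrected step are level-shifted even though they were never flagged;
  this is intrinsic to removing step discontinuities and mirrors standard
  spline (MARA-type) correction.
- **Band-pass.** 3rd-order Butterworth, 0.01–0.1 Hz, applied
  forward–backward (zero phase).  Steady-state passband gain at 0.05 Hz
  is within 0.2%; attenuation at 1 Hz (cardiac) far exceeds 20 dB; DC is
  removed.  The filter rings for a few minutes near the 0.01 Hz edge,
  which is irrelevant for the ≈10-minute runs analyzed here but matters
  for short test signals (tests measure steady-state segments).
- **Beer–Lambert inversion.** The 2×2 system uses natural-log-scale molar
  extinction coefficients (standard compiled values × ln 10) shipped as a
  data table, DPF 6.0 at both wavelengths, SD 3 cm.  Because the shipped
  table, the log convention and the inversion are mutually consistent, the
  outputs are *relative* concentration changes on an arbitrary scale;
  per-channel z-scoring downstream makes all network and group statistics
  scale-free.  A base-10 convention can be swapped in coherently by
  replacing the table.
- **Epoching.** Trial averages use a −2…+15 s window, baseline-corrected
  by the −2…0 s mean; partial epochs at recording edges are dropped and
  counted.  The per-subject activation scalar entering group tests is the
  mean of the trial-averaged curve over 0–10 s (the response deadline);
  the peak is available as an option.  Z-scoring precedes averaging, so
  curves are in z units.
- **Behavior.** Accuracy = correct/total trials; the RT summary averages
  correct trials only (errors and misses would otherwise conflate speed
  with failure); it is undefined (NaN) when no trial is correct.

Only ΔHbO continues into network analysis; ΔHbR is computed and retained
in outputs but unused downstream.

## Network construction and metrics

Connectivity is pairwise Pearson correlation over the full preprocessed
run (a task-window-restricted variant can be obtained by slicing the
series before calling `connectivity`).  Binarization modes:

- *sparsity* (default for group comparison): keep the K = round(T·78)
  largest positive coefficients, so every subject's graph has identical
  edge count and metric differences reflect arrangement, not density.
  Ties at the cutoff resolve toward the smaller (i, j) index.
- *correlation*: connect pairs with r ≥ T.

Negative correlations never form edges in either mode.

Metric conventions: nodal clustering is 0 for degree < 2; Lp averages hop
distances over *connected* ordered pairs, with the disconnected-pair count
reported alongside (no infinite or harmonic imputation); Eg assigns
disconnected pairs zero inverse distance.  Note an interaction worth
remembering when reading sparse-threshold results: a graph that breaks
into dense modules gets a *short* Lp (only within-module pairs counted)
while Eg drops — Lp and Eg answer different questions under
fragmentation.

The null model is Maslov–Sneppen degree-preserving rewiring (via
networkx double-edge swaps, 10·|E| swaps per null, 100 nulls), the
standard "comparable random network" for σ.  Degenerate degree sequences
that admit no swap (e.g. stars) fall back to the observed graph's values
with a warning.  All null ensembles are seeded; sweep entries derive
their seeds from (master seed, grid index), so a single-threshold run
reproduces the corresponding sweep entry exactly.

## Synthetic data generator

The generator emulates the acquisition above; per subject it draws, in
ΔHbO micromolar units:

- **Task response**: boxcars spanning each stimulus–response interval,
  convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
  ratio 1/6), peak-normalized, scaled by per-channel amplitudes
  (defaults: TD-like 1.0 µM everywhere; DS-like 0.1 µM on channels 1, 8, 9
  and 1.0 µM elsewhere), a per-subject log-normal gain (σ = 0.15) and
  small per-channel jitter (σ = 0.05).
- **Slow network fluctuations** (0.8 µM): band-limited (0.01–0.1 Hz)
  Gaussian processes with a controlled correlation structure, via the
  Cholesky factor of a target matrix.  The target is a banded spatial
  lattice over the channel ordering — pairs at distance d ≤ 4 couple with
  strength 0.8^d — whose beyond-nearest-neighbor couplings are relocated
  to random pairs with the group's rewiring probability (TD 0.05, DS
  0.65); the nearest-neighbor chain is never moved, keeping every latent
  graph connected.  Low rewiring yields clustered lattice-like
  thresholded graphs with long paths; high rewiring converts local
  structure into long-range shortcuts — shorter paths and higher global
  efficiency, the "more random" topology attributed to the DS-like group.
  The assembled matrix is projected to the nearest valid correlation
  matrix (eigenvalue clipping + diagonal renormalization).
- **Physiology**: sinusoids at subject-level frequencies drawn from the
  cardiac (1–1.5 Hz, 0.2 µM), respiratory (0.2–0.5 Hz, 0.1 µM) and
  Mayer-wave (0.08–0.12 Hz, 0.3 µM) bands with channel-random phases,
  plus 0.05 µM white noise.  The Mayer band deliberately overlaps the
  analysis band — the classic fNIRS confound.
- **Motion artifacts** (rate 0/min by default, configurable): step
  offsets and exponentially decaying spikes in the optical-density
  domain with exponential inter-arrival times.
- **Behavior**: subject-mean RTs are log-normal matching the emulated
  group means/SDs (DS 3562 ms, between-subject SD 1285 ms; TD 1202 ms,
  SD 294 ms — SEM×√n of the emulated study conditions); trial RTs are
  log-normal around the subject mean (CV 0.25), truncated at the 10 s
  deadline (late trials become misses).  Accuracy is Bernoulli per trial
  (DS 0.86, TD 0.958); in the TD-like group the per-subject accuracy is
  coupled to the subject's gain (+0.3 per unit gain above 1), injecting a
  recoverable positive activation–accuracy correlation at the pre-motor
  channel.

ΔHbR is −0.3·ΔHbO (the typical anticorrelated fraction).  Latent
concentrations pass through the *same* forward Beer–Lambert matrix the
preprocessing inverts, onto per-channel baseline intensities; the
noise-free round trip is therefore exact to numerical precision, and it
is verified end-to-end to ≪1% relative RMSE.

**Design history of the topology model.**  The obvious "two communities,
reassign channels at random" scheme does not yield the intended contrast:
relabeling communities leaves graphs exactly as modular as before, and
under the excluded-pair Lp convention a modular graph that fragments at
sparse thresholds looks *shorter*, not longer.  Several variants
(cliques + bridges, degree-preserving swaps of the latent graph, mixing
toward a uniform correlation matrix) each recovered one direction of the
clustered-vs-random contrast but not both, mostly through fragmentation
artifacts.  The banded-lattice-with-relocated-couplings design was
adopted because every latent graph stays connected by construction, so
measured sparsity-matched graphs differ in arrangement (lattice vs
shortcuts) rather than in fragmentation.  These choices were fixed before
the test suite was frozen.

**What the generator does not emulate**: optical photon transport (the
forward model is the same 2×2 MBLL the inverse uses), superficial/scalp
hemodynamics and short-separation channels, serially correlated
(1/f-type) measurement noise, wavelength-dependent baseline drifts, or
age/sex covariates.  Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind injected*, under realistic
band-limited noise — not that it is robust to every artifact of real
pediatric recordings.

## Statistics

Group comparisons are independent-samples t tests; Welch is the default
throughout (with 7 vs 6 subjects a paired design is impossible, and the
Welch form exactly reproduces a t statistic reconstructed from group
means and SEMs via `t = (m₁−m₂)/√(se₁²+se₂²)`).  Effect sizes are
Cohen's d with (n₁−1, n₂−1)-weighted pooled SD.  FDR control is
Benjamini–Hochberg step-up by default; Storey's q-value with λ = 0.5 is
available (`method="storey"`).  Families are: the 13 channels for
activation tests, and the threshold grid per metric for sweep tests;
sweep results also report contiguous significant ranges (uncorrected p by
default, as threshold-wise network comparisons are conventionally
reported; q-based ranges available).  Brain–behavior coupling is a
within-group Pearson correlation (n ≥ 3 required).  Post-hoc power is
deliberately out of scope.

Calibration is tested by simulation: the null rejection rate of the
channel family (any q < 0.05 among 13 channels, 200 replicates at
n = 7 vs 6) must stay within Monte-Carlo bounds of the nominal level, and
the n = 6 correlation null must exceed |r| = 0.811 (the two-tailed α=0.05
critical value) ≈5% of the time.

## Numerical and reproducibility choices

- Every stochastic step takes an explicit seed; subject streams derive
  from `SeedSequence([master, subject])`, latent topology from
  `SeedSequence([master, subject, 1])`, sweep nulls from
  `SeedSequence([master, grid_index])`.  Identical config + seed is
  bit-identical.
- CSV outputs use `repr` float formatting and round-trip parsing, so
  write → read → write is byte-stable; SNIRF (HDF5) round-trips at
  float64 precision.
- The acceptance script uses the sparsity grid 0.2–0.6 (step 0.02) — the
  central, well-conditioned part of the sweep where graphs are neither
  fragmentary nor near-complete — with 100 nulls per point; the test
  suite's shared full-pipeline fixture uses the same range at step 0.05,
  a problem size chosen to keep the default run pleasant while leaving
  the conclusions unchanged.
- Degenerate inputs fail loudly and specifically: constant channels name
  the channel (z-score, connectivity), non-positive intensities name the
  first offending sample, empty epochs/trial logs raise, metric-sweep
  grid points with fewer than two finite values per group are skipped
  and logged.

## Known limitations

- n = 13 nodes is small; graph metrics at fixed sparsity are strongly
  constrained by edge count, and group differences in Eg/Lp are of order
  0.01–0.1 — detectable in direction, not dramatic in magnitude.
- The excluded-pair Lp convention makes Lp non-monotone and
  interpretable only jointly with the disconnected-pair count at sparse
  thresholds.
- The sparsity-mode tie rule (lexicographic) is deterministic but
  arbitrary; ties are measure-zero for real data.
- Storey's estimator is unstable for families as small as 13; BH is the
  default for that reason.
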