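# Default end-to-end run: simulate the two-group dataset, preprocess,
# build connectivity networks, sweep thresholds and run group statistics.
seed: 0
simulate:
  n_ds: 7
  n_td: 6
  n_trials: 32
  motion_rate_per_min: 0.0
preprocess:
  band_low_hz: 0.01
  band_high_hz: 0.1
  motion_window_s: 1.0
  motion_amp_threshold: 0.5
  motion_std_threshold: 5.0
  spline_smoothing: 0.99
  activation_mode: mean
network:
  mode: sparsity
  grid_start: 0.1
  grid_stop: 0.9
  grid_step: 0.02
  n_null: 100
stats:
  alpha: 0.05
  fdr_method: bh
  t_variant: welch
  behavior_channel: CH08
output:
  save_recordings: false
  figures: true
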