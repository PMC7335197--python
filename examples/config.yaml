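# Example configuration for `axoncal run` / `axoncal simulate`.
# Omitted keys fall back to the package defaults (shown in comments).

session:
  n_trials: 100
  frame_rate: 30.0          # Hz
  trial_duration: 9.0       # s, trial-based acquisition sweep
  quiet_window: 2.0         # s before stimulus onset
  response_window: 2.0      # s during which licks are scored
  min_intertrial_gap: 4.5   # s; onsets are never closer than 13.5 s
  stim_fraction: 0.8        # 80% stimulus trials, split evenly C2/B2
  seed: 42

behavior:
  p_lick: {C2: 0.85, B2: 0.30, none: 0.10}
  rt_mean: 0.29             # s, first-lick reaction time
  rt_sd: 0.18

population:
  n_axons: 24
  class_proportions: {VPM_like: 0.4, POmFO_like: 0.3, POmHO_like: 0.3}
  noise_sd: 1.0             # fluorescence units
  within_axon_corr: 0.9     # shared/independent noise split per axon
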