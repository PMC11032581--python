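seed: 1
arena:
  side_length: 4.0
  border_margin: 0.3
  min_return: 3.6
  max_return: 4.0
  origin:
  - 0.0
  - 0.0
agent:
  heading_noise_kappa:
    A: 22.797266319526
    B: 12.823462304733376
    C: 8.207015875029361
  distance_gain_mean: 1.0
  distance_gain_sd: 0.12
  encoding_noise_sd: 0.0
  oob_propensity: 0.6
  participant_sd_heading_deg: 4.0
  participant_sd_log_gain: 0.05
cohort:
  n_participants: 20
  p_fh: 0.62
  p_apoe4: 0.32
  p_female: 0.65
  caide_pmf:
  - 0.01378311994362495
  - 0.034774926623955135
  - 0.0714932179986777
  - 0.11976871927704895
  - 0.1634940311305693
  - 0.18186131831948635
  - 0.16483851922527404
  - 0.12174664738703558
  - 0.07327152882179014
  - 0.03593299627985434
  - 0.014359243102278608
  - 0.0046757318904049475
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  age_range:
  - 43.0
  - 66.0
  education_range:
  - 10.0
  - 24.0
  effect_sizes: []
  seed: 1
grid:
  n_voxels: 200
  true_orientation: 23.0
  n_fold: 6
  modulation_amplitude: 1.0
  noise_sd: 0.8
  tr: 2.531
  n_events: 72
  orientation_jitter_sd: 0.0
  drift_deg_per_run: 0.0
  signal_drift: 0.0
  event_duration: 2.0
  event_gap: 3.5
  event_response: 1.0
  heading_kappa: 0.0
  hrf: spm
  seed: 1
n_elasticnet_permutations: 50
out_dir: demo_run
log_level: INFO
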