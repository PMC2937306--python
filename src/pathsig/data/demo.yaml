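# Small end-to-end demo: an in-vitro two-arm experiment, a projected tumor
# cohort in which high pathway activity is protective, and the optimal
# Kaplan-Meier stratification of the resulting scores.
seed: 1
out_dir: pathsig_demo
invitro:
  n_probes: 500
  n_reps: 3
  time_points: ["4h", "12h"]
  frac_de: 0.1
  effect_scale: 2.0
  noise_scale: 0.5
filter:
  fold: 2.0
  min_obs: 2
signature:
  rho: 0.01
  g: 4.0
cohort:
  n_tumors: 120
  activity_sd: 1.0
  noise_scale: 0.3
survival:
  log_hr: -1.0
  base_rate: 0.1
  censor_rate: 0.02
stratify:
  min_group_frac: 0.1
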