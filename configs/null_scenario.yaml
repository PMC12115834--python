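name: null_scenario
genotypes:
- control
- silenced
attacks:
  n_per_genotype: 60
  speed_log_median: 0.15
  speed_log_sigma: 0.45
  peak_time_mean_ms: 30.0
  peak_time_sd_ms: 7.0
  outcome_model:
    v_ref: 0.167
    intercept:
      control: -1.0
      silenced: -1.0
    slope:
      control: 10.0
      silenced: 10.0
  capture_end_distance:
    control: 2.0
    silenced: 2.0
  escape_distance: 4.0
ethograms:
  n:
    control: 80
    silenced: 80
  takeoff_prob:
    control: 0.85
    silenced: 0.85
  reaction_mean_ms: 60.0
  reaction_sd_ms: 6.0
  short_mode_weight:
    control: 0.7
    silenced: 0.7
  stimulus_rv: 10.0
trials:
  n_trials: 8
  n_per_group: 100
  p_eaten:
    control: 0.2
    silenced: 0.2
  wcb_n_trials: 10
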