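# Alcohol-preferring ("msP-like") cohort profile: more wake, shorter bouts
# (fragmented sleep), more quiet wake in the light phase, smaller slow waves
# with a blunted early-to-late decline, sparser/slower/smaller spindles.
# State budgets are the reference group means rescaled to sum to 1440 min
# (printed values sum to 1438.7).
name: msp-like
target_state_minutes:
  W: 727.3
  N: 566.7
  R: 146.0
mean_episode_duration:   # seconds
  W: 100.0
  N: 80.0
  R: 56.0
dark_wake_bias: 1.8
sw_rate_early: 6.5
sw_rate_late: 4.5
sw_amp_mean: 70.0
spindle_rate: 1.0
spindle_freq_mean: 13.3
spindle_amp_mean: 20.0
emg_rms:                 # µV
  active_wake: 40.0
  quiet_wake: 5.2
  NREM: 5.0
  REM: 3.0
quiet_wake_fraction_light: 0.6144
quiet_wake_fraction_dark: 0.2
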