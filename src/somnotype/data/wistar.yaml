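# Outbred control ("Wistar-like") cohort profile.
# State budgets are the group means of the reference cohort; bout durations,
# dark-phase bias and event rates are the generator's calibrated defaults.
name: wistar-like
target_state_minutes:
  W: 683.8
  N: 612.3
  R: 143.8
mean_episode_duration:   # seconds
  W: 120.0
  N: 96.0
  R: 60.0
dark_wake_bias: 1.8
sw_rate_early: 9.0       # slow waves per NREM minute, start of light period
sw_rate_late: 4.5        # ... end of light period (homeostatic decline)
sw_amp_mean: 90.0        # µV, mean negative-peak amplitude
spindle_rate: 2.0        # spindles per NREM minute
spindle_freq_mean: 14.0  # Hz
spindle_amp_mean: 25.0   # µV, envelope peak
emg_rms:                 # µV
  active_wake: 40.0
  quiet_wake: 5.2
  NREM: 5.0
  REM: 3.0
quiet_wake_fraction_light: 0.379
quiet_wake_fraction_dark: 0.2
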