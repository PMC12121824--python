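# somnotype

Sleep phenotyping of 24-hour rodent EEG/EMG recordings.

Rodent polysomnography — frontal and parietal EEG plus neck EMG, scored in
4-s epochs as Wake / NREM / REM — is the workhorse assay for comparing
sleep between rat or mouse lines.  `somnotype` turns a recording and its
hypnogram into a complete per-animal phenotype:

* **Sleep architecture** — state minutes per 24 h and per light/dark phase,
  episodes (runs ≥ 8 s), sleep attempts (sleep < 20 s between wake > 20 s),
  brief awakenings (wake < 16 s between sleep), NREM latency, the six state
  transition counts, and the sleep fragmentation index (wake episodes per
  hour of total sleep).
* **Spectral analysis** — per-4-s-epoch FFT power at 0.25 Hz resolution,
  absolute band powers per vigilance state (SWA 0.5–4, low/high/total theta,
  sigma 12–15, beta 15–30 Hz), the wake theta/beta ratio, hourly SWA and
  sigma time courses and their first-vs-twelfth-hour change scores (the
  homeostatic Process-S readout).
* **Motor activity** — quiet vs active wake from EMG epoch power, thresholded
  at the 95th percentile of NREM EMG power.
* **NREM events** — slow waves (zero-crossing detection with
  amplitude/duration admissibility: deflections 0.1–2 s, peaks 10–400 µV,
  peak-to-peak ≥ 30 µV) and sleep spindles (12–18 Hz; moving correlation
  ≥ 0.75 with the sigma-filtered signal, moving-RMS z ≥ 1.5, duration
  0.5–15 s), summarised over early (first 3 h of light) and late (last 3 h
  of light) sleep.
* **Synthetic polysomnography** — a seeded generator producing 24-h
  recordings (Markov-chain hypnogram, state-gated coloured-noise EEG with
  planted slow waves and spindles, state-dependent EMG tone) with exact
  ground truth, plus two calibrated cohort profiles: an outbred control
  ("Wistar-like") and an alcohol-preferring, sleep-fragmented line
  ("msP-like").

See `docs/methods.md` for the models, conventions, and what the synthetic
validation does and does not establish.

## Worked example

```python
import somnotype as st
from somnotype.pipeline import run_pipeline
from somnotype.config import AnalysisConfig

profile = st.wistar_like()
rec, hyp, truth = st.simulate_animal(profile, seed=1, fs=128.0)

cfg = AnalysisConfig(eeg_channels=["EEG Frontal"])
report = run_pipeline(rec, hyp, cfg, animal_id="wistar-01")

mins = report.architecture["minutes_per_state"]
print(f"minutes W/N/R: {mins['W']:.1f} / {mins['N']:.1f} / {mins['R']:.1f}")
print(f"fragmentation index: {report.architecture['fragmentation_index']:.1f}")
print(f"quiet wake (light): {report.wake_classification['percent_quiet']['light']:.1f} %")
sw = report.slow_waves["EEG Frontal"]
print(f"slow waves early/late: {sw['early']['incidence_per_min']:.1f} / "
      f"{sw['late']['incidence_per_min']:.1f} per NREM min")
```

prints

```
minutes W/N/R: 681.6 / 584.5 / 173.9
fragmentation index: 22.6
quiet wake (light): 36.8 %
slow waves early/late: 7.2 / 4.9 per NREM min
```

This animal spends ~11.4 h awake (the control profile's 24-h budget is
683.8 min), 36.8% of its light-phase wake is quiet wake (profile target
37.9%), and its slow-wave incidence declines from early to late sleep —
the homeostatic dissipation of sleep pressure the generator plants and the
pipeline measures.

The same analysis runs from the shell on EDF + hypnogram-CSV files:

```sh
somnotype simulate --profile msp --n-animals 5 --seed 0 --out-dir sim/
somnotype run sim/msp-like-000.edf sim/msp-like-000_hypnogram.csv --out-dir out/
somnotype cohort sim/manifest.csv --out-dir out/
```

`run` writes a JSON report and tidy CSV metric/event tables per animal;
`cohort` adds a long-format table and group mean ± SD summaries.

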