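# Methods

`somnotype` analyses 24-hour rodent polysomnography (two EEG derivations and
one EMG channel, scored in 4-s epochs as Wake/NREM/REM) and ships a synthetic
generator that produces such recordings with exact ground truth.  This note
documents the models, the parameter choices, and what the synthetic
validation does and does not establish.

## Analysis conventions

All thresholds live in `somnotype.config.AnalysisConfig` and can be
overridden from a YAML file; the defaults are the standard settings used
throughout:

| setting | default | meaning |
|---|---|---|
| epoch length | 4 s | scoring resolution |
| episode rule | ≥ 8 s | minimum bout counted as an episode |
| sleep attempt | sleep run < 20 s between wake runs > 20 s (strict) | combined NREM+REM runs |
| brief awakening | wake run < 16 s between sleep runs | recording-edge wake not counted |
| NREM latency | first NREM run ≥ 20 s from lights-on | NaN when absent |
| fragmentation index | wake episodes / h of total sleep | per-hour is this package's unit |
| EMG threshold | 95th percentile of NREM epoch power | linear interpolation between order statistics |
| bands (Hz) | SWA 0.5–4, low θ 5–8, high θ 8–12, total θ 5–12, σ 12–15, β 15–30 | shared edges assigned exclusively to one band so adjacent bands are exactly additive; the 4–5 Hz gap is unassigned |

Spectra are per-epoch Hann-tapered periodograms at 0.25 Hz resolution; bin
powers are scaled so that their sum up to Nyquist equals the Hann-weighted
mean square of the (mean-removed) epoch — an exact Parseval identity under
the window-corrected convention.  Band powers are absolute (µV²), not
normalised.  Artifact-flagged epochs keep their state label for architecture
metrics but are excluded from spectral and event analyses.

Hourly SWA (NREM 0.5–4 Hz power) and sigma time courses align to lights-on;
the light-period SWA change is hour 1 minus hour 12, the sigma change is
hour 12 minus hour 1 (sigma rises as pressure dissipates, so both changes
are positive in a normal animal).

Epoch/phase bookkeeping: lights-on at t = 0, 12 h light / 12 h dark; an
epoch (or episode) belongs to the phase of its start time.

## Event detection

**Slow waves** are found on the 0.5–4 Hz zero-phase band-passed signal
(Butterworth, two second-order sections, forward–backward) as
positive→negative→positive zero-crossing triplets.  A candidate becomes an
event when all criteria hold: each deflection 0.1–2 s, each peak 10–400 µV,
peak-to-peak ≥ 30 µV, and 1/duration within 0.5–4 Hz.  Slope is
peak-to-peak amplitude over the trough-to-crest time.  Amplitudes are
measured on the filtered signal, so a planted 115 µV wave reads a few
percent lower (passband droop) — the tests account for this.

**Spindles** are found on the 12–18 Hz band.  Two decision signals are
computed: A, the 300-ms moving Pearson correlation between broadband and
sigma-filtered signal; and B, the 200-ms moving RMS of the sigma-filtered
signal z-scored against its NREM distribution in the analysed window.  The
two indicator series (A ≥ 0.75, B ≥ 1.5) are combined *softly*: both
conditions must hold together over a sustained core (smoothed indicator sum
> 1 for ≥ 0.4 s), and the event extends to the surrounding stretch where at
least one condition holds nearby (smoothed sum > 0.15).  Events closer than
500 ms merge; survivors must last 0.5–15 s and have a mean frequency in
12–18 Hz.  A naive per-sample OR of the two thresholds was tried first and
produced ~0.4 precision on synthetic NREM — chance sigma bursts chain across
the merge gap — which is why the sustained-core combination is used; the
published thresholds, window lengths and merge gap are unchanged.

Per-event frequency is the envelope²-weighted Hilbert instantaneous
frequency over the event body (envelope ≥ half its maximum), seeded on a
wider 10–20 Hz order-4 filtered copy and refined by two passes that
re-filter the raw segment in a ±2.5 Hz band centred on the running estimate.
Two measured biases motivate this: the 12 Hz detection-band edge shaves the
lower spectral lobe of ~13.3 Hz events (≈ +0.2 Hz on noise-free waveforms),
and peak-spacing estimators are additionally biased by envelope modulation
and noise peak-splitting (up to +0.7 Hz).  The refined estimator recovers
planted frequencies within ≈ 0.05 Hz (Wistar-like) to ≈ 0.15 Hz (msP-like,
whose 13.3 Hz events sit closest to the band edge).

Both detectors analyse early sleep (non-artifact NREM epochs in the first
3 h of the light period) and late sleep (last 3 h of the light period)
separately; incidence is events per NREM minute of the window.

## Synthetic polysomnography

**Hypnogram.**  A first-order Markov chain over {W, N, R} at epoch
resolution, with piecewise-constant transition matrices for the light and
dark phase.  Within-phase stationary distributions are derived from the
profile's 24-h state budget with wake prevalence scaled by
`dark_wake_bias` (default 1.8: wake-minute ratio dark:light).  NREM/REM
stay-probabilities encode the profile bout durations
(`p_stay = 1 − epoch_s/duration`); exit splits are solved from flow balance,
with Wake→REM entries fixed at 1% of wake exits (rare but present, as in
scored data).  The wake bout duration is a *soft* target: the flow-balance
system is generally infeasible with one wake bout duration in both phases,
so it is clipped per phase to the nearest feasible value — wake bouts come
out longer in the dark phase, which is also the physiological pattern.
Realized 24-h state minutes are unbiased for the budget (50-seed means land
within ~5 min of target, well inside one between-animal SD).

**EEG.**  Background = white floor (2 µV RMS) plus four band-limited
Gaussian components (0.5–4, 5–12, 12–18, 18–45 Hz) whose RMS is gated per
state (NREM: elevated delta; REM: elevated theta; wake: broadband), with
0.5-s smoothed gain transitions.  The NREM delta floor is deliberately
modest (5 µV RMS): in this generative model the discrete planted slow waves
carry the slow activity, and the floor is the residue — this is what makes
planted-event precision measurable at all.  Slow waves are biphasic
half-sine pulses (negative then positive deflection, 0.2–0.5 s each;
negative amplitude log-normal around the profile mean, clipped to 40–350 µV;
positive ≈ 0.55× negative), planted at a rate that declines linearly from
`sw_rate_early` to `sw_rate_late` across the light period and recovers
across the dark period — the Process-S dynamics the SWA time course
measures.  Spindles are Gaussian-enveloped sinusoids (0.6–1.2 s, frequency
normal around the profile mean ± 0.3 Hz, envelope peak log-normal) at a rate
modulated ±25% anti-correlated with sleep pressure, so sigma power rises
from early to late sleep.  Planted events never overlap, lie entirely inside
NREM runs, and every parameter is recorded in the `GroundTruth` registry.
An optional negative-control mode plants events violating exactly one
detector criterion each (slow waves at the peak-to-peak floor of ~20 µV with
0.2-s deflections; 0.28-s spindle bursts) for specificity tests, and an
artifact mode corrupts a chosen fraction of wake epochs with 150 µV
broadband bursts, flagged in the ground-truth hypnogram.

**EMG.**  White noise with per-epoch RMS drawn log-normally around the
profile's state values (active wake 40, quiet wake 5.2, NREM 5, REM 3 µV;
spreads 0.2–0.3 log-units).  Quiet wake is assigned per wake epoch from the
profile's per-phase quiet fractions.  Note a deliberate tension: the
95th-percentile NREM threshold can only yield a non-trivial quiet/active
split if quiet-wake EMG overlaps the upper NREM range, so quiet wake sits
just above the NREM median but below its 95th percentile — the profile-mean
ordering active ≫ quiet > NREM ≥ REM holds, but per-epoch quiet-vs-NREM
ordering is probabilistic by design.

**Cohort profiles.**  `wistar_like()` (outbred control) and `msp_like()`
(alcohol-preferring) are YAML files under `somnotype/data/`.  State budgets:
683.8/612.3/143.8 and 726.6/566.2/145.9 min W/N/R (the latter rescaled by
×1.0009 so the budget sums to 1440 min).  Quiet-wake fractions 0.379 vs
0.6144 (light phase; 0.2 dark).  The msP-like profile is more fragmented
(shorter bouts), has smaller slow waves (70 vs 90 µV) with a blunted
early→late rate decline (6.5→4.5 vs 9→4.5 per NREM minute), and sparser
(1 vs 2 per NREM minute), slower (13.3 vs 14.0 Hz) and smaller (20 vs 25 µV)
spindles.  Where the underlying study reports only a direction, magnitudes
were chosen once as physiologically plausible effect sizes (≈ 20–50%
reductions) that keep events detectable in both lines.

## What the synthetic validation shows — and does not

Passing tests establish that: the architecture metrics equal a brute-force
oracle exactly; the spectral pipeline satisfies Parseval and bandwidth
identities; the EMG threshold equals the interpolated-percentile definition;
the detectors recover planted events (recall ≈ 0.95, precision ≈ 0.95–0.99
at Wistar-like amplitudes), reject single-criterion violations (specificity
≈ 0.91 pooled), and agree within 15% with independently coded reference
implementations; and the full pipeline recovers the cohort-level phenotype
directions and calibration targets encoded in the profiles.

They do not establish performance on real EEG: real slow waves and spindles
are not half-sine pulses or Gaussian-enveloped sinusoids, real backgrounds
are non-stationary with state-transition dynamics, ultradian NREM/REM
cycling is absent from the Markov model (bout durations are geometric), and
real artifact morphology is richer than broadband bursts.  Detector
operating points on real data should be validated against manual scoring.

## Numerical choices and degenerate inputs

Filters are zero-phase Butterworth (SOS, forward–backward), two sections for
detection (order-4 magnitude), four for spindle frequency estimation.  Epoch
slicing requires `epoch_s × fs` to be integral; half-open 0-based sample
intervals.  Undefined quantities (no qualifying NREM run, empty state
selection, zero sleep time, empty event set) are NaN, serialized as `null`
in report JSON.  Empty sleep windows yield zero incidence and NaN feature
means rather than errors in the pipeline; calling a detector directly on an
empty window raises.  Simulation sizes used in tests and the acceptance
script (30-min event fixtures at 256 Hz, 24-h cohorts of 5 + 5 animals at
128 Hz, single EEG channel) were chosen as the smallest sizes at which the
Monte-Carlo tolerances hold comfortably; the generator's sampling-rate floor
is 100 Hz (beta band must stay below Nyquist with margin).

## EDF and hypnogram formats

Recordings are written as 16-bit EDF with one-second records and per-channel
physical scaling in µV (a compact writer in `somnotype.edf`); reading goes
through `mne` with explicit µV conversion, so round-trips are exact to the
16-bit quantization step.  Hypnograms use a CSV dialect
(`epoch_index,state,artifact`, states W/N/R with common aliases) or a
compact single-line string form; ground truth is a JSON sidecar.
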