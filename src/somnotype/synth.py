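"""Synthetic 24-h polysomnography with ground truth.

The generator produces labelled recordings with the statistical structure the
downstream analysis assumes:

* **Hypnogram** — a first-order Markov chain over {Wake, NREM, REM} at epoch
  resolution with piecewise-constant (light vs dark) transition matrices.
  Stay probabilities encode the profile's mean bout durations
  (``p_stay = 1 - epoch_s / mean_episode_duration``); exit splits are solved
  from flow balance so that the within-phase stationary distribution matches
  the profile's state budget, with the dark-phase wake prevalence scaled by
  ``dark_wake_bias``.  Direct Wake→REM entries are allowed with a small
  probability (they occur in scored data, rarely).
* **EEG** — 1/f-flavoured background built from state-gated band-limited
  Gaussian components (NREM: elevated 0.5–4 Hz; REM: elevated 5–12 Hz;
  Wake: broadband), plus planted slow waves (biphasic half-sine pulses whose
  per-minute rate declines linearly across the light period and recovers
  across the dark period — the homeostatic SWA dynamics) and sleep spindles
  (Gaussian-enveloped sinusoids).  Planted events never overlap and lie
  entirely inside NREM runs; the exact parameters of every event are
  returned as :class:`GroundTruth`.
* **EMG** — Gaussian noise whose per-epoch RMS is set by state (and by the
  quiet/active plan for wake epochs) with log-normal epoch-to-epoch
  variability, emulating muscle tone.

Everything is a pure function of (arguments, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import Hypnogram, NREM, PSGRecording, REM, STATES, WAKE, write_edf, write_hypnogram
from .profiles import CohortProfile, ProfileError

#: Wake→REM entry probability (share of wake exits); near zero but nonzero.
WAKE_TO_REM_EXIT_SHARE = 0.01

#: Background EEG component levels, µV RMS per (band, state).  The delta floor
#: is deliberately modest: in this generative model NREM slow activity is
#: carried by the planted discrete slow waves, the floor is the non-slow-wave
#: residue.
BACKGROUND_RMS = {
    # band edges Hz        W     N     R
    (0.5, 4.0):   {WAKE: 2.0, NREM: 5.0, REM: 2.0},
    (5.0, 12.0):  {WAKE: 4.0, NREM: 2.0, REM: 8.0},
    (12.0, 18.0): {WAKE: 2.0, NREM: 3.0, REM: 2.0},
    (18.0, 45.0): {WAKE: 4.0, NREM: 2.5, REM: 3.0},
}
#: Broadband white floor, µV RMS (all states).
WHITE_RMS = 2.0

#: Log-normal sigma of per-epoch EMG RMS variability, per state key.
EMG_RMS_SPREAD = {"active_wake": 0.3, "quiet_wake": 0.2, "NREM": 0.25, "REM": 0.2}

#: Amplitude of injected broadband movement artifacts, µV RMS.
ARTIFACT_RMS = 150.0


@dataclass(frozen=True)
class PlantedSW:
    """A planted slow wave: one negative then one positive half-sine."""
    start: float      # s
    neg_amp: float    # µV, magnitude of the negative peak
    pos_amp: float    # µV
    neg_dur: float    # s
    pos_dur: float    # s

    @property
    def duration(self) -> float:
        return self.neg_dur + self.pos_dur

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class PlantedSpindle:
    """A planted spindle: Gaussian-enveloped sinusoid."""
    start: float      # s
    duration: float   # s
    freq: float       # Hz
    amp: float        # µV, envelope peak

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class GroundTruth:
    """Registry of everything the generator planted, for scoring detectors."""
    hypnogram: Hypnogram
    slow_waves: list[PlantedSW] = field(default_factory=list)
    spindles: list[PlantedSpindle] = field(default_factory=list)
    #: negative controls, each violating exactly one detection criterion
    sub_threshold_slow_waves: list[PlantedSW] = field(default_factory=list)
    sub_threshold_spindles: list[PlantedSpindle] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "epoch_s": self.hypnogram.epoch_s,
            "labels": "".join(self.hypnogram.labels.tolist()),
            "artifact": self.hypnogram.artifact.astype(int).tolist(),
            "slow_waves": [asdict(e) for e in self.slow_waves],
            "spindles": [asdict(e) for e in self.spindles],
            "sub_threshold_slow_waves": [asdict(e) for e in self.sub_threshold_slow_waves],
            "sub_threshold_spindles": [asdict(e) for e in self.sub_threshold_spindles],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        hyp = Hypnogram(np.array(list(d["labels"])), epoch_s=d["epoch_s"],
                        artifact=np.array(d["artifact"], dtype=bool))
        return cls(
            hypnogram=hyp,
            slow_waves=[PlantedSW(**e) for e in d["slow_waves"]],
            spindles=[PlantedSpindle(**e) for e in d["spindles"]],
            sub_threshold_slow_waves=[PlantedSW(**e) for e in d["sub_threshold_slow_waves"]],
            sub_threshold_spindles=[PlantedSpindle(**e) for e in d["sub_threshold_spindles"]],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

def _phase_targets(profile: CohortProfile) -> dict[str, dict[str, float]]:
    """Within-phase stationary state fractions implied by the 24-h budget and
    the dark-phase wake bias (equal-length phases average to the budget)."""
    pi = profile.state_fractions()
    b = profile.dark_wake_bias
    out = {}
    for phase, wake_scale in (("light", 2.0 / (1.0 + b)), ("dark", 2.0 * b / (1.0 + b))):
        w = pi[WAKE] * wake_scale
        if not 0 < w < 1:
            raise ProfileError(f"dark_wake_bias {b} pushes {phase} wake share to {w:.3f}")
        rest = (1.0 - w) / (1.0 - pi[WAKE])
        out[phase] = {WAKE: w, NREM: pi[NREM] * rest, REM: pi[REM] * rest}
    return out


def _transition_matrix(profile: CohortProfile, pi: dict[str, float],
                       epoch_s: float) -> np.ndarray:
    """3x3 transition matrix (order W, N, R) with stationary distribution
    ``pi`` and the profile's mean bout durations.

    The NREM/REM bout durations and the state budget are hard targets; the
    wake bout duration is a soft target, clipped per phase to the nearest
    value compatible with flow balance (wake bouts are naturally longer in
    the phase where wake is prevalent).
    """
    for s in STATES:
        if profile.mean_episode_duration[s] < epoch_s:
            raise ProfileError(
                f"mean_episode_duration[{s}]={profile.mean_episode_duration[s]}s "
                f"shorter than epoch ({epoch_s}s)"
            )
    # bout-start flow per epoch for the hard-constrained sleep states
    q_n = pi[NREM] / (profile.mean_episode_duration[NREM] / epoch_s)
    q_r = pi[REM] / (profile.mean_episode_duration[REM] / epoch_s)
    q_w_target = pi[WAKE] / (profile.mean_episode_duration[WAKE] / epoch_s)

    eps = WAKE_TO_REM_EXIT_SHARE
    q_w = q_w_target
    for _ in range(20):  # fixed point: clip wake flow into the feasible band
        r_nr = (q_r - eps * q_w) / q_n
        if not 0.0 <= r_nr <= 1.0:
            raise ProfileError(
                f"profile {profile.name!r} admits no Markov chain with the "
                f"requested budgets/bout durations (exit share N->R = {r_nr:.3f})"
            )
        r_nw = 1.0 - r_nr
        q_w = float(np.clip(q_w_target, q_n * r_nw, q_n * r_nw + q_r))
    r_rw = float(np.clip((q_w - q_n * r_nw) / q_r, 0.0, 1.0))
    r_rn = 1.0 - r_rw

    p_stay = {
        WAKE: 1.0 - q_w / pi[WAKE],
        NREM: 1.0 - epoch_s / profile.mean_episode_duration[NREM],
        REM: 1.0 - epoch_s / profile.mean_episode_duration[REM],
    }
    P = np.array([
        [p_stay[WAKE], (1 - p_stay[WAKE]) * (1 - eps), (1 - p_stay[WAKE]) * eps],
        [(1 - p_stay[NREM]) * r_nw, p_stay[NREM], (1 - p_stay[NREM]) * r_nr],
        [(1 - p_stay[REM]) * r_rw, (1 - p_stay[REM]) * r_rn, p_stay[REM]],
    ])
    return P


def simulate_hypnogram(profile: CohortProfile, duration_h: float = 24.0,
                       epoch_s: float = 4.0, seed: int = 0) -> Hypnogram:
    """Simulate a scored hypnogram for a 12h:12h light/dark schedule.

    Lights-on is at t=0; phases alternate every 12 h.  The chain starts from
    the light-phase stationary distribution.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if abs(3600.0 / epoch_s - round(3600.0 / epoch_s)) > 1e-9:
        raise ValueError("epoch_s must divide 3600")
    targets = _phase_targets(profile)
    P = {ph: _transition_matrix(profile, targets[ph], epoch_s) for ph in ("light", "dark")}
    cum = {ph: np.cumsum(P[ph], axis=1) for ph in P}

    n_epochs = int(round(duration_h * 3600.0 / epoch_s))
    t = np.arange(n_epochs) * epoch_s
    is_light = (t % 86400.0) < 43200.0

    rng = np.random.default_rng(seed)
    u = rng.random(n_epochs + 1)
    pi0 = np.array([targets["light"][s] for s in STATES])
    state = int(np.searchsorted(np.cumsum(pi0), u[0]))
    labels = np.empty(n_epochs, dtype="<U1")
    for i in range(n_epochs):
        labels[i] = STATES[state]
        c = cum["light" if is_light[i] else "dark"][state]
        state = int(np.searchsorted(c, u[i + 1]))
    return Hypnogram(labels, epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _nrem_runs_samples(hyp: Hypnogram, fs: float) -> list[tuple[int, int]]:
    """Contiguous NREM blocks as half-open sample intervals."""
    spe = int(round(hyp.epoch_s * fs))
    lab = hyp.labels
    runs = []
    i = 0
    while i < lab.size:
        if lab[i] == NREM:
            j = i
            while j < lab.size and lab[j] == NREM:
                j += 1
            runs.append((i * spe, j * spe))
            i = j
        else:
            i += 1
    return runs


def _state_envelope(hyp: Hypnogram, fs: float, n: int,
                    per_state: dict[str, float], smooth_s: float = 0.5) -> np.ndarray:
    spe = int(round(hyp.epoch_s * fs))
    env = np.repeat([per_state[s] for s in hyp.labels], spe).astype(np.float64)
    env = env[:n] if env.size >= n else np.pad(env, (0, n - env.size), mode="edge")
    w = max(int(round(smooth_s * fs)), 1)
    if w > 1:
        env = sps.convolve(env, np.ones(w) / w, mode="same")
    return env


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    hi = min(hi, 0.499 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / rms if rms > 0 else y


def _sw_waveform(fs: float, ev: PlantedSW) -> np.ndarray:
    n_neg = max(int(round(ev.neg_dur * fs)), 2)
    n_pos = max(int(round(ev.pos_dur * fs)), 2)
    t_neg = np.arange(n_neg) / n_neg
    t_pos = np.arange(n_pos) / n_pos
    return np.concatenate([-ev.neg_amp * np.sin(np.pi * t_neg),
                           ev.pos_amp * np.sin(np.pi * t_pos)])


def _spindle_waveform(fs: float, ev: PlantedSpindle,
                      rng: np.random.Generator) -> np.ndarray:
    n = max(int(round(ev.duration * fs)), 2)
    t = np.arange(n) / fs
    c = ev.duration / 2.0
    envelope = ev.amp * np.exp(-0.5 * ((t - c) / (ev.duration / 6.0)) ** 2)
    phase = rng.uniform(0, 2 * np.pi)
    return envelope * np.sin(2 * np.pi * ev.freq * (t - c) + phase)


def _pressure_frac(t: float) -> float:
    """Position along the homeostatic cycle: 0 at lights-on (high pressure),
    1 at lights-off, falling back to 0 across the dark period."""
    tod = t % 86400.0
    return tod / 43200.0 if tod < 43200.0 else 1.0 - (tod - 43200.0) / 43200.0


def _sw_rate_at(t: float, profile: CohortProfile) -> float:
    """Slow-wave rate (per NREM minute) at time t: linear decline across the
    light period, linear recovery across the dark period (Process S)."""
    f = _pressure_frac(t)
    return profile.sw_rate_early + (profile.sw_rate_late - profile.sw_rate_early) * f


def _spindle_rate_at(t: float, profile: CohortProfile) -> float:
    """Spindle rate: anti-correlated with sleep pressure (sigma power rises
    from early to late sleep), ±25% around the profile mean."""
    return profile.spindle_rate * (0.75 + 0.5 * _pressure_frac(t))


def _place_events(rng, run_start_s, run_end_s, rate_fn, dur_fn, occupied,
                  margin_s=0.05):
    """Plant non-overlapping events in one NREM run by Poisson thinning.

    ``rate_fn(t)`` is events/min; ``dur_fn()`` draws a duration.  Returns the
    accepted (start, duration) pairs and updates ``occupied`` in place.
    """
    span = run_end_s - run_start_s
    rmax = max(rate_fn(run_start_s), rate_fn(run_end_s)) / 60.0
    n_cand = rng.poisson(rmax * span)
    out = []
    for t0 in np.sort(rng.uniform(run_start_s, run_end_s, n_cand)):
        if rng.random() > rate_fn(t0) / 60.0 / rmax:
            continue
        dur = dur_fn()
        if t0 + dur + margin_s > run_end_s:
            continue
        if any(t0 < e + margin_s and t0 + dur + margin_s > s for s, e in occupied):
            continue
        occupied.append((t0, t0 + dur))
        out.append((t0, dur))
    return out


def synthesize_eeg(hyp: Hypnogram, profile: CohortProfile, fs: float = 512.0,
                   seed: int = 0, negative_controls: bool = False,
                   artifact_fraction: float = 0.0) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one EEG channel (µV) plus the exact planting registry.

    Parameters
    ----------
    negative_controls : bool
        Also plant sub-threshold events, each violating exactly one detector
        criterion (slow waves with peak-to-peak < 30 µV; spindles shorter
        than 0.5 s), recorded separately in the ground truth.
    artifact_fraction : float
        Fraction of wake epochs to corrupt with high-amplitude broadband
        artifacts; the returned ground-truth hypnogram has them flagged.
    """
    if fs < 100:
        raise ValueError(f"fs={fs} Hz too low: the beta band is unresolvable")
    rng = np.random.default_rng(seed)
    spe = int(round(hyp.epoch_s * fs))
    n = hyp.n_epochs * spe

    sig = WHITE_RMS * rng.standard_normal(n)
    for (lo, hi), levels in BACKGROUND_RMS.items():
        if lo >= 0.499 * fs:
            continue
        sig += _band_noise(rng, n, fs, lo, hi) * _state_envelope(hyp, fs, n, levels)

    art = hyp.artifact.copy()
    if artifact_fraction > 0:
        wake_idx = np.flatnonzero(hyp.labels == WAKE)
        n_art = int(round(artifact_fraction * wake_idx.size))
        chosen = rng.choice(wake_idx, size=n_art, replace=False) if n_art else []
        for i in chosen:
            sig[i * spe:(i + 1) * spe] += ARTIFACT_RMS * rng.standard_normal(spe)
            art[i] = True

    truth = GroundTruth(
        hypnogram=Hypnogram(hyp.labels.copy(), epoch_s=hyp.epoch_s, artifact=art),
        seed=seed,
    )

    amp_sigma = 0.25
    for s0, e0 in _nrem_runs_samples(hyp, fs):
        run_s, run_e = s0 / fs, e0 / fs
        occupied: list[tuple[float, float]] = []

        # slow waves (rate follows the homeostatic time course)
        for t0, dur in _place_events(rng, run_s, run_e,
                                     lambda t: _sw_rate_at(t, profile),
                                     lambda: rng.uniform(0.4, 1.0), occupied):
            neg_dur = rng.uniform(0.2, min(0.5, dur - 0.2))
            pos_dur = dur - neg_dur
            neg = float(np.clip(profile.sw_amp_mean *
                                rng.lognormal(0.0, amp_sigma), 40.0, 350.0))
            pos = float(np.clip(neg * rng.uniform(0.45, 0.65), 15.0, 350.0))
            ev = PlantedSW(t0, neg, pos, neg_dur, pos_dur)
            i0 = int(round(t0 * fs))
            w = _sw_waveform(fs, ev)
            sig[i0:i0 + w.size] += w[: n - i0]
            truth.slow_waves.append(ev)

        # spindles (rate anti-correlated with sleep pressure)
        for t0, dur in _place_events(rng, run_s, run_e,
                                     lambda t: _spindle_rate_at(t, profile),
                                     lambda: rng.uniform(0.6, 1.2), occupied):
            ev = PlantedSpindle(
                t0, dur,
                float(np.clip(rng.normal(profile.spindle_freq_mean, 0.3), 12.2, 17.8)),
                float(np.clip(profile.spindle_amp_mean * rng.lognormal(0.0, 0.2), 8.0, 80.0)),
            )
            i0 = int(round(t0 * fs))
            w = _spindle_waveform(fs, ev, rng)
            sig[i0:i0 + w.size] += w[: n - i0]
            truth.spindles.append(ev)

        if negative_controls:
            # slow waves failing only the >=30 µV peak-to-peak criterion,
            # at the structural floor (both peaks just above the 10 µV
            # admissibility minimum, so no other criterion is violated)
            for t0, dur in _place_events(rng, run_s, run_e, lambda t: 2.0,
                                         lambda: 0.4, occupied):
                ev = PlantedSW(t0, 10.3, 10.0, 0.2, 0.2)
                i0 = int(round(t0 * fs))
                w = _sw_waveform(fs, ev)
                sig[i0:i0 + w.size] += w[: n - i0]
                truth.sub_threshold_slow_waves.append(ev)
            # spindle bursts failing only the >=0.5 s duration criterion
            for t0, dur in _place_events(rng, run_s, run_e, lambda t: 2.0,
                                         lambda: 0.28, occupied):
                ev = PlantedSpindle(
                    t0, dur,
                    float(np.clip(rng.normal(profile.spindle_freq_mean, 0.3), 12.2, 17.8)),
                    float(np.clip(profile.spindle_amp_mean * rng.lognormal(0.0, 0.2), 8.0, 80.0)),
                )
                i0 = int(round(t0 * fs))
                w = _spindle_waveform(fs, ev, rng)
                sig[i0:i0 + w.size] += w[: n - i0]
                truth.sub_threshold_spindles.append(ev)

    truth.slow_waves.sort(key=lambda e: e.start)
    truth.spindles.sort(key=lambda e: e.start)
    truth.sub_threshold_slow_waves.sort(key=lambda e: e.start)
    truth.sub_threshold_spindles.sort(key=lambda e: e.start)
    return sig, truth


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

def quiet_wake_plan(hyp: Hypnogram, profile: CohortProfile, seed: int = 0,
                    light_h: float = 12.0) -> np.ndarray:
    """Boolean quiet-wake flag per *wake* epoch, drawn from the profile's
    per-phase quiet-wake fractions."""
    from .architecture import phase_of_epoch
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51]))
    phases = phase_of_epoch(hyp, light_h=light_h)
    wake = hyp.labels == WAKE
    frac = np.where(phases[wake] == "light",
                    profile.quiet_wake_fraction_light,
                    profile.quiet_wake_fraction_dark)
    return rng.random(wake.sum()) < frac


def synthesize_emg(hyp: Hypnogram, profile: CohortProfile, fs: float = 512.0,
                   seed: int = 0, plan: np.ndarray | None = None) -> np.ndarray:
    """Synthesize the EMG channel (µV): white noise with state-set epoch RMS.

    ``plan`` flags quiet wake per wake epoch (default: drawn from the
    profile's quiet-wake fractions).  Per-epoch RMS varies log-normally
    around the profile's state values, emulating tonus fluctuations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE3]))
    wake = hyp.labels == WAKE
    if plan is None:
        plan = quiet_wake_plan(hyp, profile, seed=seed)
    plan = np.asarray(plan, dtype=bool)
    if plan.size != wake.sum():
        raise ValueError(
            f"quiet-wake plan length {plan.size} != number of wake epochs {wake.sum()}"
        )

    key = np.empty(hyp.n_epochs, dtype="<U11")
    key[hyp.labels == NREM] = "NREM"
    key[hyp.labels == REM] = "REM"
    wk = np.where(plan, "quiet_wake", "active_wake")
    key[wake] = wk
    rms = np.array([profile.emg_rms[k] *
                    rng.lognormal(0.0, EMG_RMS_SPREAD[k]) for k in key])

    spe = int(round(hyp.epoch_s * fs))
    env = np.repeat(rms, spe)
    return env * rng.standard_normal(env.size)


# ---------------------------------------------------------------------------
# Whole-animal convenience
# ---------------------------------------------------------------------------

def simulate_animal(profile: CohortProfile, seed: int = 0, fs: float = 512.0,
                    duration_h: float = 24.0, epoch_s: float = 4.0,
                    negative_controls: bool = False,
                    artifact_fraction: float = 0.0,
                    out_dir=None, animal_id: str | None = None,
                    ) -> tuple[PSGRecording, Hypnogram, GroundTruth]:
    """Simulate one animal: hypnogram, frontal+parietal EEG and EMG.

    The parietal channel shares the frontal channel's planted events (as real
    bilateral derivations do) and differs by independent sensor noise.  When
    ``out_dir`` is given, writes ``<id>.edf``, ``<id>_hypnogram.csv`` and
    ``<id>_truth.json``.
    """
    ss = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)
    hyp = simulate_hypnogram(profile, duration_h=duration_h, epoch_s=epoch_s,
                             seed=int(ss[0]))
    eeg_f, truth = synthesize_eeg(hyp, profile, fs=fs, seed=int(ss[1]),
                                  negative_controls=negative_controls,
                                  artifact_fraction=artifact_fraction)
    sensor = np.random.default_rng(int(ss[2]))
    eeg_p = eeg_f + 2.0 * sensor.standard_normal(eeg_f.size)
    emg = synthesize_emg(truth.hypnogram, profile, fs=fs, seed=int(ss[3]))
    rec = PSGRecording(
        channels={"EEG Frontal": eeg_f, "EEG Parietal": eeg_p, "EMG": emg},
        fs=fs,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aid = animal_id or f"{profile.name}-{seed}"
        write_edf(rec, out / f"{aid}.edf")
        write_hypnogram(truth.hypnogram, out / f"{aid}_hypnogram.csv")
        truth.to_json(out / f"{aid}_truth.json")
    return rec, truth.hypnogram, truth
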