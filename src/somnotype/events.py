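"""NREM slow-wave and sleep-spindle detection and summaries.

Slow waves are detected on the 0.5–4 Hz zero-phase band-passed signal as
zero-crossing triplets (one negative then one positive deflection) subject to
amplitude/duration admissibility criteria:

* negative and positive deflection durations each 0.1–2 s,
* negative and positive peak amplitudes each 10–400 µV,
* peak-to-peak amplitude >= 30 µV,
* wave frequency (1/duration) within 0.5–4 Hz.

Spindles are detected on the 12–18 Hz band.  Two decision signals are
computed over the NREM samples of the analysis window: the moving Pearson
correlation (300 ms) between the broadband and sigma-filtered signal, and the
moving RMS (200 ms) of the sigma-filtered signal z-scored against its NREM
distribution in the window.  The two threshold indicators (correlation >=
0.75, z >= 1.5) are combined softly: both conditions must hold together over
a sustained core, and the event extends to the surrounding stretch where at
least one condition holds nearby.  Candidate events closer than 500 ms are
merged; events are kept when their duration is 0.5–15 s and their mean
instantaneous frequency falls in 12–18 Hz.

Both detectors operate only on non-artifact NREM epochs of the requested
sleep window; analysis windows are *early* (first 3 h of the light period)
and *late* (last 3 h of the light period) sleep, the high- and low-pressure
ends of the homeostatic cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import Hypnogram, NREM, PSGRecording

# slow-wave admissibility criteria
SW_FREQ = (0.5, 4.0)            # Hz band and 1/duration range
SW_DUR_NEG = (0.1, 2.0)         # s
SW_DUR_POS = (0.1, 2.0)         # s
SW_AMP_NEG = (10.0, 400.0)      # µV (magnitude)
SW_AMP_POS = (10.0, 400.0)      # µV
SW_PTP_MIN = 30.0               # µV

# spindle criteria
SP_FREQ = (12.0, 18.0)          # Hz
SP_DUR = (0.5, 15.0)            # s
SP_CORR_THRESH = 0.75
SP_RMS_Z_THRESH = 1.5
SP_CORR_WIN_S = 0.3
SP_RMS_WIN_S = 0.2
SP_MERGE_GAP_S = 0.5
SP_SOFT_SMOOTH_S = 0.1
SP_MIN_CORE_S = 0.4

FILTER_ORDER = 2                # SOS sections; 4th-order magnitude response


@dataclass(frozen=True)
class SWCriteria:
    """Slow-wave admissibility criteria (defaults are the standard settings)."""
    freq: tuple[float, float] = SW_FREQ
    dur_neg: tuple[float, float] = SW_DUR_NEG
    dur_pos: tuple[float, float] = SW_DUR_POS
    amp_neg: tuple[float, float] = SW_AMP_NEG
    amp_pos: tuple[float, float] = SW_AMP_POS
    ptp_min: float = SW_PTP_MIN


@dataclass(frozen=True)
class SpindleCriteria:
    """Spindle detection thresholds and moving-window lengths."""
    freq: tuple[float, float] = SP_FREQ
    dur: tuple[float, float] = SP_DUR
    corr_thresh: float = SP_CORR_THRESH
    rms_z_thresh: float = SP_RMS_Z_THRESH
    corr_win_s: float = SP_CORR_WIN_S
    rms_win_s: float = SP_RMS_WIN_S
    merge_gap_s: float = SP_MERGE_GAP_S
    soft_smooth_s: float = SP_SOFT_SMOOTH_S
    min_core_s: float = SP_MIN_CORE_S


@dataclass(frozen=True)
class SWEvent:
    start: float
    mid_zero_crossing: float
    end: float
    neg_peak_amp: float   # µV, magnitude
    pos_peak_amp: float   # µV
    ptp: float            # µV
    duration: float       # s
    slope: float          # µV/s, ptp over neg-peak -> pos-peak time
    frequency: float      # Hz, 1/duration


@dataclass(frozen=True)
class SpindleEvent:
    start: float
    end: float
    duration: float
    amplitude: float        # µV, max peak-to-peak of sigma-filtered signal
    mean_frequency: float   # Hz
    n_oscillations: int     # positive peaks of the sigma-filtered signal


@dataclass
class SleepWindow:
    """A labelled set of NREM epoch indices (early or late light-period sleep)."""
    label: str
    epochs: np.ndarray

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.size)


def sleep_windows(hyp: Hypnogram, light_h: float = 12.0,
                  span_h: float = 3.0) -> dict[str, SleepWindow]:
    """Early/late sleep windows: non-artifact NREM epochs within the first and
    last ``span_h`` hours of the (first) light period."""
    t = hyp.epoch_times()
    nrem = (hyp.labels == NREM) & ~hyp.artifact
    early = nrem & (t < span_h * 3600.0)
    late = nrem & (t >= (light_h - span_h) * 3600.0) & (t < light_h * 3600.0)
    return {
        "early": SleepWindow("early", np.flatnonzero(early)),
        "late": SleepWindow("late", np.flatnonzero(late)),
    }


def _window_segments(hyp: Hypnogram, window: SleepWindow, fs: float
                     ) -> list[tuple[int, int]]:
    """Contiguous epoch blocks of the window as half-open sample intervals."""
    if window.n_epochs == 0:
        raise ValueError(f"sleep window {window.label!r} is empty")
    spe = int(round(hyp.epoch_s * fs))
    idx = np.sort(window.epochs)
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    out = []
    for block in np.split(idx, breaks):
        out.append((int(block[0]) * spe, (int(block[-1]) + 1) * spe))
    return out


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
              order: int = FILTER_ORDER) -> np.ndarray:
    sos = sps.butter(order, [lo, min(hi, 0.499 * fs)],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


# ---------------------------------------------------------------------------
# Slow waves
# ---------------------------------------------------------------------------

def detect_slow_waves(rec: PSGRecording, hyp: Hypnogram, window: SleepWindow,
                      channel: str = "EEG Frontal",
                      criteria: SWCriteria = SWCriteria()) -> list[SWEvent]:
    """Detect slow waves in the NREM samples of one sleep window."""
    fs = rec.fs
    c = criteria
    segments = _window_segments(hyp, window, fs)
    settle_s = 3.0 / c.freq[0]  # a few periods of the band's low edge
    if max(e - s for s, e in segments) < settle_s * fs:
        raise ValueError(
            f"window {window.label!r}: longest NREM segment shorter than the "
            f"filter settling length ({settle_s:.0f} s)"
        )
    filt = _bandpass(rec.channel(channel), fs, *c.freq)

    events: list[SWEvent] = []
    for s0, e0 in segments:
        seg = filt[s0:e0]
        neg = seg < 0
        down = np.flatnonzero(~neg[:-1] & neg[1:]) + 1   # pos -> neg crossing
        up = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1     # neg -> pos crossing
        if down.size < 2 or up.size < 1:
            continue
        for k in range(down.size - 1):
            t0 = down[k]
            ups = up[(up > t0) & (up < down[k + 1])]
            if ups.size != 1:
                continue
            t1, t2 = int(ups[0]), int(down[k + 1])
            neg_dur = (t1 - t0) / fs
            pos_dur = (t2 - t1) / fs
            dur = (t2 - t0) / fs
            if not (c.dur_neg[0] <= neg_dur <= c.dur_neg[1]):
                continue
            if not (c.dur_pos[0] <= pos_dur <= c.dur_pos[1]):
                continue
            if not (1.0 / c.freq[1] <= dur <= 1.0 / c.freq[0]):
                continue
            i_neg = t0 + int(np.argmin(seg[t0:t1]))
            i_pos = t1 + int(np.argmax(seg[t1:t2]))
            neg_amp = float(-seg[i_neg])
            pos_amp = float(seg[i_pos])
            ptp = neg_amp + pos_amp
            if not (c.amp_neg[0] <= neg_amp <= c.amp_neg[1]):
                continue
            if not (c.amp_pos[0] <= pos_amp <= c.amp_pos[1]):
                continue
            if ptp < c.ptp_min:
                continue
            events.append(SWEvent(
                start=(s0 + t0) / fs,
                mid_zero_crossing=(s0 + t1) / fs,
                end=(s0 + t2) / fs,
                neg_peak_amp=neg_amp, pos_peak_amp=pos_amp, ptp=ptp,
                duration=dur, slope=ptp / ((i_pos - i_neg) / fs),
                frequency=1.0 / dur,
            ))
    events.sort(key=lambda e: e.start)
    return events


def sw_summary(events: list[SWEvent], window: SleepWindow,
               epoch_s: float = 4.0) -> dict[str, float]:
    """Mean amplitude/slope/duration/frequency and incidence (events per NREM
    minute of the window)."""
    nrem_min = window.n_epochs * epoch_s / 60.0
    out = {"n_events": float(len(events)),
           "incidence_per_min": len(events) / nrem_min if nrem_min else math.nan}
    for name, attr in [("amplitude_uv", "ptp"), ("slope_uv_per_s", "slope"),
                       ("duration_s", "duration"), ("frequency_hz", "frequency")]:
        vals = [getattr(e, attr) for e in events]
        out[name] = float(np.mean(vals)) if vals else math.nan
    return out


# ---------------------------------------------------------------------------
# Spindles
# ---------------------------------------------------------------------------

def _moving_corr(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    mx = uniform_filter1d(x, w, mode="nearest")
    my = uniform_filter1d(y, w, mode="nearest")
    mxy = uniform_filter1d(x * y, w, mode="nearest")
    mx2 = uniform_filter1d(x * x, w, mode="nearest")
    my2 = uniform_filter1d(y * y, w, mode="nearest")
    cov = mxy - mx * my
    var = np.clip(mx2 - mx ** 2, 0, None) * np.clip(my2 - my ** 2, 0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var)
    return np.nan_to_num(r)


def detect_spindles(rec: PSGRecording, hyp: Hypnogram, window: SleepWindow,
                    channel: str = "EEG Frontal",
                    criteria: SpindleCriteria = SpindleCriteria()) -> list[SpindleEvent]:
    """Detect sleep spindles in the NREM samples of one sleep window."""
    fs = rec.fs
    c = criteria
    segments = _window_segments(hyp, window, fs)
    w_corr = max(int(round(c.corr_win_s * fs)), 3)
    w_rms = max(int(round(c.rms_win_s * fs)), 3)
    if max(e - s for s, e in segments) < max(w_corr, w_rms):
        raise ValueError(
            f"window {window.label!r}: NREM segments shorter than the moving "
            f"analysis window"
        )
    x = rec.channel(channel)
    sigma = _bandpass(x, fs, *c.freq)
    # wider, steeper filter for per-event frequency estimation: the detection
    # band's 12 Hz edge would otherwise shave the lower spectral lobe of
    # events near it and bias their frequency upward
    sigma_est = _bandpass(x, fs, c.freq[0] - 2.0, c.freq[1] + 2.0, order=4)
    corr = _moving_corr(x, sigma, w_corr)
    mrms = np.sqrt(np.clip(uniform_filter1d(sigma ** 2, w_rms, mode="nearest"), 0, None))

    # z-score the moving RMS against the NREM distribution of this window
    nrem_mask = np.zeros(x.size, dtype=bool)
    for s0, e0 in segments:
        nrem_mask[s0:e0] = True
    mu, sd = mrms[nrem_mask].mean(), mrms[nrem_mask].std()
    z = (mrms - mu) / sd if sd > 0 else np.zeros_like(mrms)

    # soft threshold combination: the per-sample indicators are averaged over
    # a short window; an event needs a sustained core where both conditions
    # hold (smoothed sum > 1 for >= the smoothing length) and extends to its
    # weak envelope (smoothed sum > 0.5, at least one condition nearby)
    ind = (corr >= c.corr_thresh).astype(float) + (z >= c.rms_z_thresh).astype(float)
    sm = uniform_filter1d(ind, max(int(round(c.soft_smooth_s * fs)), 1),
                          mode="nearest")
    strong = sm > 1.0
    weak = sm > 0.15
    core_len = max(int(round(c.min_core_s * fs)), 1)
    gap = int(round(c.merge_gap_s * fs))

    events: list[SpindleEvent] = []
    for s0, e0 in segments:
        spans = _runs_with_core(weak[s0:e0], strong[s0:e0], core_len)
        # merge candidate events closer than the merge gap
        merged: list[list[int]] = []
        for a, b, ca, cb in spans:
            if merged and a - merged[-1][1] < gap:
                merged[-1][1] = b
                merged[-1][3] = cb
            else:
                merged.append([a, b, ca, cb])
        for a, b, ca, cb in merged:
            dur = (b - a) / fs
            if not (c.dur[0] <= dur <= c.dur[1]):
                continue
            seg_sig = sigma[s0 + a:s0 + b]
            # successive peaks of a 12-18 Hz oscillation are at least one
            # cycle of the band's upper edge apart
            min_dist = max(int(fs / c.freq[1]) - 1, 1)
            peaks, _ = sps.find_peaks(seg_sig, height=0.0, distance=min_dist)
            if peaks.size < 2:
                continue
            mean_freq = _instantaneous_frequency(
                x, sigma_est, s0 + a, s0 + b, fs)
            if not (c.freq[0] <= mean_freq <= c.freq[1]):
                continue
            events.append(SpindleEvent(
                start=(s0 + a) / fs, end=(s0 + b) / fs, duration=dur,
                amplitude=float(seg_sig.max() - seg_sig.min()),
                mean_frequency=mean_freq,
                n_oscillations=int(peaks.size),
            ))
    events.sort(key=lambda e: e.start)
    return events


def _weighted_inst_freq(seg: np.ndarray, fs: float) -> float:
    """Envelope-squared-weighted Hilbert instantaneous frequency over the
    samples whose analytic envelope reaches at least half its maximum —
    the oscillation body, where the event dominates the background."""
    analytic = sps.hilbert(seg)
    env = np.abs(analytic)
    inst = np.diff(np.unwrap(np.angle(analytic))) * fs / (2.0 * np.pi)
    sel = env[:-1] >= 0.5 * env.max()
    if not sel.any():
        return float("nan")
    w = env[:-1][sel] ** 2
    return float(np.sum(inst[sel] * w) / np.sum(w))


def _instantaneous_frequency(x: np.ndarray, sig_est: np.ndarray, a: int, b: int,
                             fs: float, pad_s: float = 1.0) -> float:
    """Per-event mean frequency with iterative symmetric-band refinement.

    A first estimate on the wide-band filtered signal seeds two refinement
    passes that re-filter the raw segment in a band centred on the running
    estimate; the symmetric band cancels the frequency pull of the flat
    background (which is one-sided for events near a band edge).
    """
    pad = int(round(pad_s * fs))
    lo = max(a - pad, 0)
    f = _weighted_inst_freq(sig_est[lo:b + pad][a - lo:b - lo], fs)
    for _ in range(2):
        if not np.isfinite(f):
            return float("nan")
        band = (max(f - 2.5, 0.5), min(f + 2.5, 0.49 * fs))
        seg = _bandpass(x[lo:b + pad], fs, *band, order=2)[a - lo:b - lo]
        f = _weighted_inst_freq(seg, fs)
    return f


def _runs_with_core(weak: np.ndarray, strong: np.ndarray, core_len: int
                    ) -> list[tuple[int, int, int, int]]:
    """Contiguous weak runs containing a contiguous strong stretch of at
    least ``core_len`` samples; returns (start, end, core_start, core_end)."""
    idx = np.flatnonzero(weak)
    if idx.size == 0:
        return []
    out = []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    for grp in np.split(idx, breaks):
        a, b = int(grp[0]), int(grp[-1]) + 1
        s = strong[a:b]
        sidx = np.flatnonzero(s)
        if sidx.size < core_len:
            continue
        sbreaks = np.flatnonzero(np.diff(sidx) > 1) + 1
        best = max(np.split(sidx, sbreaks), key=len)
        if best.size >= core_len:
            out.append((a, b, a + int(best[0]), a + int(best[-1]) + 1))
    return out


def spindle_summary(events: list[SpindleEvent], window: SleepWindow,
                    epoch_s: float = 4.0) -> dict[str, float]:
    """Mean spindle features and incidence in spindles per NREM minute."""
    nrem_min = window.n_epochs * epoch_s / 60.0
    out = {"n_events": float(len(events)),
           "incidence_per_min": len(events) / nrem_min if nrem_min else math.nan}
    for name, attr in [("amplitude_uv", "amplitude"), ("duration_s", "duration"),
                       ("frequency_hz", "mean_frequency"),
                       ("n_oscillations", "n_oscillations")]:
        vals = [getattr(e, attr) for e in events]
        out[name] = float(np.mean(vals)) if vals else math.nan
    return out


def events_table(events: list) -> pd.DataFrame:
    """One row per detected event (CSV-ready)."""
    return pd.DataFrame([asdict(e) for e in events])


def match_events(detected_intervals, true_intervals, tol_s: float = 0.1
                 ) -> tuple[int, int, int]:
    """Greedy 1:1 matching of detections to planted events by overlap.

    A detection matches an unclaimed planted event when their intervals
    overlap (with ``tol_s`` slack at the edges).  Returns (true_pos,
    false_pos, false_neg); used by validation tests and the acceptance
    script.
    """
    claimed = np.zeros(len(true_intervals), dtype=bool)
    tp = 0
    for ds, de in detected_intervals:
        for j, (s, e) in enumerate(true_intervals):
            if not claimed[j] and ds <= e + tol_s and de >= s - tol_s:
                claimed[j] = True
                tp += 1
                break
    return tp, len(detected_intervals) - tp, len(true_intervals) - tp
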