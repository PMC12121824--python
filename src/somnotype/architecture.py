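"""Sleep-architecture metrics derived from the hypnogram.

Definitions follow the standard rodent scoring conventions used throughout
the package:

* a *run* is a maximal block of consecutive epochs in the same state;
* an *episode* is a run lasting >= 8 s;
* a *sleep attempt* is a combined NREM+REM sleep run < 20 s flanked on both
  sides by wake runs > 20 s (both comparisons strict);
* a *brief awakening* is a wake run < 16 s occurring between sleep runs;
* NREM latency is the time from lights-on to the first NREM run >= 20 s;
* the *sleep fragmentation index* is the number of wake episodes per hour of
  total sleep (NREM + REM) time.

Artifact-flagged epochs keep their state label here; artifact exclusion
applies to spectral and event analyses only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import Hypnogram, NREM, REM, STATES, WAKE

#: Episode rule: runs must last at least this long (seconds).
EPISODE_MIN_S = 8.0
#: Sleep-attempt rule: sleep run strictly shorter, flanking wake strictly longer.
ATTEMPT_SLEEP_MAX_S = 20.0
ATTEMPT_WAKE_MIN_S = 20.0
#: Brief awakening: wake run strictly shorter than this, between sleep runs.
BRIEF_AWAKENING_MAX_S = 16.0
#: NREM latency: first NREM run at least this long (inclusive).
NREM_LATENCY_MIN_S = 20.0

TRANSITION_PAIRS = [
    (WAKE, NREM), (WAKE, REM),
    (NREM, WAKE), (NREM, REM),
    (REM, WAKE), (REM, NREM),
]


@dataclass(frozen=True)
class Episode:
    """A maximal same-state run lasting >= 8 s."""
    state: str
    start: float      # seconds from recording start
    duration: float   # seconds


@dataclass(frozen=True)
class Run:
    state: str
    start: float
    duration: float


def state_runs(hyp: Hypnogram) -> list[Run]:
    """Maximal same-state runs covering the hypnogram, in temporal order."""
    labels = hyp.labels
    if labels.size == 0:
        raise ValueError("empty hypnogram")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [
        Run(state=str(labels[s]), start=s * hyp.epoch_s,
            duration=(e - s) * hyp.epoch_s)
        for s, e in zip(starts, ends)
    ]


def episodes(runs: list[Run], min_s: float = EPISODE_MIN_S) -> list[Episode]:
    """Runs lasting at least ``min_s`` (inclusive), as episodes."""
    return [Episode(r.state, r.start, r.duration) for r in runs if r.duration >= min_s]


def _merged_sleep_runs(runs: list[Run]) -> list[Run]:
    """Merge contiguous NREM/REM runs into combined sleep runs; wake kept as is."""
    merged: list[Run] = []
    for r in runs:
        kind = WAKE if r.state == WAKE else "S"
        if merged and (merged[-1].state == kind):
            last = merged[-1]
            merged[-1] = Run(kind, last.start, last.duration + r.duration)
        else:
            merged.append(Run(kind, r.start, r.duration))
    return merged


def sleep_attempts(runs: list[Run], sleep_max_s: float = ATTEMPT_SLEEP_MAX_S,
                   wake_min_s: float = ATTEMPT_WAKE_MIN_S) -> int:
    """Count combined sleep runs < 20 s flanked by wake runs > 20 s."""
    m = _merged_sleep_runs(runs)
    n = 0
    for i in range(1, len(m) - 1):
        cur, prev, nxt = m[i], m[i - 1], m[i + 1]
        if (cur.state == "S" and cur.duration < sleep_max_s
                and prev.state == WAKE and prev.duration > wake_min_s
                and nxt.state == WAKE and nxt.duration > wake_min_s):
            n += 1
    return n


def brief_awakenings(runs: list[Run], max_s: float = BRIEF_AWAKENING_MAX_S) -> int:
    """Count wake runs < 16 s flanked by sleep on both sides.

    Recording-edge wake runs are not counted: an awakening presupposes
    preceding (and here also following) sleep.
    """
    n = 0
    for i in range(1, len(runs) - 1):
        r = runs[i]
        if r.state == WAKE and r.duration < max_s:
            if runs[i - 1].state != WAKE and runs[i + 1].state != WAKE:
                n += 1
    return n


def nrem_latency(hyp: Hypnogram, lights_on_epoch: int = 0,
                 min_s: float = NREM_LATENCY_MIN_S) -> float:
    """Seconds from lights-on to the first NREM run >= 20 s, or NaN if none.

    Only NREM runs starting at or after ``lights_on_epoch`` qualify.
    """
    sub = Hypnogram(hyp.labels[lights_on_epoch:], epoch_s=hyp.epoch_s,
                    artifact=hyp.artifact[lights_on_epoch:])
    for r in state_runs(sub):
        if r.state == NREM and r.duration >= min_s:
            return r.start
    return math.nan


def transition_counts(hyp: Hypnogram) -> dict[tuple[str, str], int]:
    """Counts of adjacent-epoch state changes, keyed by ordered state pair."""
    a, b = hyp.labels[:-1], hyp.labels[1:]
    out = {}
    for src, dst in TRANSITION_PAIRS:
        out[(src, dst)] = int(np.sum((a == src) & (b == dst)))
    return out


def fragmentation_index(eps: list[Episode], hyp: Hypnogram) -> float:
    """Wake episodes per hour of total sleep (NREM+REM) time; NaN if no sleep."""
    sleep_s = float(np.sum(hyp.labels != WAKE)) * hyp.epoch_s
    if sleep_s == 0:
        return math.nan
    n_wake = sum(1 for e in eps if e.state == WAKE)
    return n_wake / (sleep_s / 3600.0)


def minutes_per_state(hyp: Hypnogram) -> dict[str, float]:
    return {s: float(np.sum(hyp.labels == s)) * hyp.epoch_s / 60.0 for s in STATES}


def time_course(hyp: Hypnogram, bin_h: float = 2.0) -> pd.DataFrame:
    """Minutes per state per time bin aligned to recording start (lights-on).

    Returns a tidy frame with columns (bin, bin_start_h, state, minutes).
    Partial trailing bins are reported with their actual content.
    """
    if bin_h <= 0:
        raise ValueError("bin_h must be positive")
    epochs_per_bin = bin_h * 3600.0 / hyp.epoch_s
    bins = np.floor(np.arange(hyp.n_epochs) / epochs_per_bin).astype(int)
    rows = []
    for b in range(bins.max() + 1):
        sel = hyp.labels[bins == b]
        for s in STATES:
            rows.append({
                "bin": b,
                "bin_start_h": b * bin_h,
                "state": s,
                "minutes": float(np.sum(sel == s)) * hyp.epoch_s / 60.0,
            })
    return pd.DataFrame(rows)


def phase_of_epoch(hyp: Hypnogram, light_h: float = 12.0) -> np.ndarray:
    """Per-epoch phase label ('light'/'dark') for a 12h:12h schedule starting
    at lights-on (t=0), by epoch start time."""
    t = hyp.epoch_times()
    period = 2 * light_h * 3600.0
    return np.where((t % period) < light_h * 3600.0, "light", "dark")


@dataclass
class ArchitectureMetrics:
    """Full per-animal architecture summary."""
    minutes_per_state: dict[str, float]
    minutes_per_state_phase: dict[str, dict[str, float]]
    episode_counts: dict[str, dict[str, int]]
    mean_bout_duration: dict[str, float]
    sleep_attempts: int
    brief_awakenings: int
    nrem_latency_s: float
    transitions: dict[str, int]
    fragmentation_index: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(hyp: Hypnogram, light_h: float = 12.0) -> ArchitectureMetrics:
    """All architecture metrics of a 24-h (or shorter) hypnogram."""
    runs = state_runs(hyp)
    eps = episodes(runs)
    phases = phase_of_epoch(hyp, light_h=light_h)

    mins_phase: dict[str, dict[str, float]] = {}
    ep_counts: dict[str, dict[str, int]] = {}
    for ph in ("light", "dark"):
        sel = hyp.labels[phases == ph]
        mins_phase[ph] = {s: float(np.sum(sel == s)) * hyp.epoch_s / 60.0 for s in STATES}
        # an episode belongs to the phase of its start time
        ep_counts[ph] = {
            s: sum(1 for e in eps
                   if e.state == s
                   and (("light" if (e.start % (2 * light_h * 3600)) < light_h * 3600
                         else "dark") == ph))
            for s in STATES
        }

    mean_bout = {}
    for s in STATES:
        durs = [e.duration for e in eps if e.state == s]
        mean_bout[s] = float(np.mean(durs)) if durs else math.nan

    return ArchitectureMetrics(
        minutes_per_state=minutes_per_state(hyp),
        minutes_per_state_phase=mins_phase,
        episode_counts=ep_counts,
        mean_bout_duration=mean_bout,
        sleep_attempts=sleep_attempts(runs),
        brief_awakenings=brief_awakenings(runs),
        nrem_latency_s=nrem_latency(hyp),
        transitions={f"{a}-{b}": v for (a, b), v in transition_counts(hyp).items()},
        fragmentation_index=fragmentation_index(eps, hyp),
    )
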