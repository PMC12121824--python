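"""Brute-force reference implementations of the sleep-architecture metrics.

Everything here works on plain Python lists of per-epoch labels with explicit
loops, independently of the package's vectorised code, and serves as the
exact oracle for the architecture module.
"""

from __future__ import annotations

import math


def runs(labels, epoch_s=4.0):
    """[(state, start_s, duration_s)] by direct scanning."""
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], i * epoch_s, (j - i) * epoch_s))
        i = j
    return out


def episodes(labels, epoch_s=4.0, min_s=8.0):
    return [r for r in runs(labels, epoch_s) if r[2] >= min_s]


def sleep_attempts(labels, epoch_s=4.0):
    # merge N/R into sleep, then scan triples
    merged = []
    for state, start, dur in runs(labels, epoch_s):
        kind = "W" if state == "W" else "S"
        if merged and merged[-1][0] == kind:
            merged[-1][2] += dur
        else:
            merged.append([kind, start, dur])
    n = 0
    for i in range(1, len(merged) - 1):
        if (merged[i][0] == "S" and merged[i][2] < 20.0
                and merged[i - 1][0] == "W" and merged[i - 1][2] > 20.0
                and merged[i + 1][0] == "W" and merged[i + 1][2] > 20.0):
            n += 1
    return n


def brief_awakenings(labels, epoch_s=4.0):
    r = runs(labels, epoch_s)
    n = 0
    for i in range(1, len(r) - 1):
        if (r[i][0] == "W" and r[i][2] < 16.0
                and r[i - 1][0] != "W" and r[i + 1][0] != "W"):
            n += 1
    return n


def nrem_latency(labels, epoch_s=4.0):
    for state, start, dur in runs(labels, epoch_s):
        if state == "N" and dur >= 20.0:
            return start
    return math.nan


def transitions(labels):
    out = {}
    for a in "WNR":
        for b in "WNR":
            if a != b:
                out[(a, b)] = 0
    for x, y in zip(labels[:-1], labels[1:]):
        if x != y:
            out[(x, y)] += 1
    return out


def fragmentation_index(labels, epoch_s=4.0):
    sleep_s = sum(epoch_s for l in labels if l != "W")
    if sleep_s == 0:
        return math.nan
    n_wake_ep = sum(1 for r in episodes(labels, epoch_s) if r[0] == "W")
    return n_wake_ep / (sleep_s / 3600.0)
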