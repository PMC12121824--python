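"""Independent, naive reference implementations of the event detectors.

These re-implement the same detection algorithms (zero-crossing slow-wave
detection; moving-correlation + moving-RMS spindle detection with the soft
threshold combination) from their descriptions, sharing no code with the
package: FIR filters instead of IIR, pandas rolling windows instead of
uniform filters, and plain Python loops instead of vectorised grouping.
They serve as the cross-implementation oracle for event counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps


def _fir_bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
                  width_hz: float = 0.5) -> np.ndarray:
    ntaps = int(round(3.0 * fs / width_hz)) | 1
    taps = sps.firwin(ntaps, [lo, min(hi, 0.499 * fs)], pass_zero=False, fs=fs)
    return sps.filtfilt(taps, [1.0], x, padlen=min(len(x) - 1, 3 * ntaps))


def ref_slow_wave_count(x: np.ndarray, fs: float,
                        freq=(0.5, 4.0), dur_neg=(0.1, 2.0), dur_pos=(0.1, 2.0),
                        amp_neg=(10.0, 400.0), amp_pos=(10.0, 400.0),
                        ptp_min=30.0) -> int:
    """Count admissible slow waves in one continuous NREM stretch."""
    filt = _fir_bandpass(x, fs, *freq, width_hz=0.4)
    count = 0
    i = 1
    n = len(filt)
    while i < n:
        # find a positive-to-negative zero crossing
        if not (filt[i - 1] >= 0 > filt[i]):
            i += 1
            continue
        t0 = i
        j = t0
        while j < n and filt[j] < 0:
            j += 1
        if j >= n:
            break
        t1 = j                      # negative-to-positive crossing
        while j < n and filt[j] >= 0:
            j += 1
        if j >= n:
            break
        t2 = j                      # next positive-to-negative crossing
        neg_d = (t1 - t0) / fs
        pos_d = (t2 - t1) / fs
        dur = (t2 - t0) / fs
        na = -min(filt[t0:t1])
        pa = max(filt[t1:t2])
        ok = (dur_neg[0] <= neg_d <= dur_neg[1]
              and dur_pos[0] <= pos_d <= dur_pos[1]
              and 1.0 / freq[1] <= dur <= 1.0 / freq[0]
              and amp_neg[0] <= na <= amp_neg[1]
              and amp_pos[0] <= pa <= amp_pos[1]
              and na + pa >= ptp_min)
        count += ok
        i = t2
    return count


def ref_spindle_count(x: np.ndarray, fs: float,
                      freq=(12.0, 18.0), dur=(0.5, 15.0),
                      corr_thresh=0.75, rms_z_thresh=1.5,
                      corr_win_s=0.3, rms_win_s=0.2, merge_gap_s=0.5,
                      smooth_s=0.1, min_core_s=0.4, weak_level=0.15) -> int:
    """Count spindles in one continuous NREM stretch (soft combination)."""
    sigma = _fir_bandpass(x, fs, *freq, width_hz=1.5)
    sx = pd.Series(x)
    sy = pd.Series(sigma)
    w_corr = int(round(corr_win_s * fs))
    corr = sx.rolling(w_corr, center=True, min_periods=1).corr(sy).to_numpy()
    corr = np.nan_to_num(corr)
    w_rms = int(round(rms_win_s * fs))
    mrms = np.sqrt(pd.Series(sigma ** 2)
                   .rolling(w_rms, center=True, min_periods=1)
                   .mean().to_numpy())
    z = (mrms - mrms.mean()) / mrms.std()

    ind = (corr >= corr_thresh).astype(float) + (z >= rms_z_thresh).astype(float)
    sm = pd.Series(ind).rolling(int(round(smooth_s * fs)), center=True,
                                min_periods=1).mean().to_numpy()
    weak = sm > weak_level
    strong = sm > 1.0

    # contiguous weak runs that contain a sustained strong core
    spans = []
    i = 0
    n = len(weak)
    core_len = int(round(min_core_s * fs))
    while i < n:
        if not weak[i]:
            i += 1
            continue
        j = i
        while j < n and weak[j]:
            j += 1
        run, best = 0, 0
        for k in range(i, j):
            run = run + 1 if strong[k] else 0
            best = max(best, run)
        if best >= core_len:
            spans.append([i, j])
        i = j
    # merge spans closer than the gap, then apply the duration rule
    merged = []
    for a, b in spans:
        if merged and a - merged[-1][1] < merge_gap_s * fs:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return sum(1 for a, b in merged if dur[0] <= (b - a) / fs <= dur[1])
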