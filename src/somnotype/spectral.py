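"""State-resolved EEG spectral analysis and EMG-based wake subclassification.

Power spectra are computed per 4-s epoch by FFT at 0.25 Hz resolution
(Hann-tapered periodogram).  Band powers are absolute power in µV² summed
over the 0.25 Hz bins of each band; the band scheme is

====
delta / SWA   0.5–4 Hz   (both edges inclusive)
low theta     5–8 Hz     (8 Hz exclusive)
high theta    8–12 Hz    (both inclusive)
total theta   5–12 Hz
sigma         12–15 Hz   (12 Hz exclusive)
beta          15–30 Hz   (15 Hz exclusive)
====

The exclusive shared edges make adjacent bands exactly additive on the
0.25 Hz grid (total theta = low + high theta; the 4–5 Hz gap is left
unassigned).  Epochs flagged as artifact carry no spectral values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Hypnogram, NREM, PSGRecording, WAKE
from .architecture import phase_of_epoch

FREQ_RES = 0.25  # Hz, fixed by the 4-s epoch length


@dataclass(frozen=True)
class Band:
    lo: float
    hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        lo_ok = freqs >= self.lo if self.lo_inclusive else freqs > self.lo
        hi_ok = freqs <= self.hi if self.hi_inclusive else freqs < self.hi
        return lo_ok & hi_ok


def default_bands() -> dict[str, Band]:
    return {
        "swa": Band(0.5, 4.0),
        "low_theta": Band(5.0, 8.0, hi_inclusive=False),
        "high_theta": Band(8.0, 12.0),
        "theta_total": Band(5.0, 12.0),
        "sigma": Band(12.0, 15.0, lo_inclusive=False),
        "beta": Band(15.0, 30.0, lo_inclusive=False),
    }


@dataclass
class EpochSpectra:
    """Per-epoch one-sided power spectra on a 0.25 Hz grid (µV² per bin).

    ``power`` has shape (n_epochs, n_freqs); artifact epochs are NaN rows.
    """
    freqs: np.ndarray
    power: np.ndarray
    states: np.ndarray
    artifact: np.ndarray
    channel: str
    epoch_s: float = 4.0

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


def windowed_mean_square(x: np.ndarray, window: str = "hann") -> np.ndarray:
    """Hann-weighted mean square of each row of ``x`` after mean removal.

    This is the time-domain quantity the per-epoch spectra integrate to
    (Parseval identity under the window-corrected convention).
    """
    x = np.atleast_2d(x)
    w = sps.get_window(window, x.shape[-1])
    xd = x - x.mean(axis=-1, keepdims=True)
    return np.sum((w * xd) ** 2, axis=-1) / np.sum(w ** 2)


def epoch_psd(rec: PSGRecording, hyp: Hypnogram, channel: str,
              fmax: float | None = 40.0, window: str = "hann") -> EpochSpectra:
    """Per-epoch FFT power spectra of one EEG channel.

    Each 4-s epoch is detrended (mean removal), Hann-tapered and transformed;
    bin powers are scaled so that their sum over all bins up to Nyquist
    equals the windowed mean square of the epoch (µV²).  The grid runs from
    0.25 Hz to ``fmax`` (default 40 Hz, capped at Nyquist); DC is dropped.
    Artifact-flagged epochs are skipped (NaN rows).
    """
    x = rec.channel(channel)
    spe = hyp.epoch_s * rec.fs
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(f"epoch_s*fs = {spe} not an integer sample count")
    spe = int(round(spe))
    if abs(hyp.epoch_s - 4.0) > 1e-9:
        raise ValueError("spectral analysis is defined on 4-s epochs")
    n_ep = min(hyp.n_epochs, rec.n_samples // spe)
    if n_ep < hyp.n_epochs:
        raise ValueError("hypnogram longer than recording")
    seg = x[: n_ep * spe].reshape(n_ep, spe)

    freqs, pxx = sps.periodogram(
        seg, fs=rec.fs, window=window, detrend="constant",
        scaling="density", axis=-1,
    )
    power = pxx * FREQ_RES  # density -> absolute power per 0.25 Hz bin

    keep = freqs >= FREQ_RES - 1e-9
    if fmax is not None:
        keep &= freqs <= min(fmax, rec.fs / 2) + 1e-9
    freqs, power = freqs[keep], power[:, keep]

    art = hyp.artifact[:n_ep].copy()
    power = power.astype(np.float64)
    power[art] = np.nan
    return EpochSpectra(freqs=freqs, power=power, states=hyp.labels[:n_ep].copy(),
                        artifact=art, channel=channel, epoch_s=hyp.epoch_s)


def band_power(spectra: EpochSpectra, band: Band | str, state: str | None = None,
               bands: dict[str, Band] | None = None) -> tuple[np.ndarray, float]:
    """Per-epoch band power and its mean over non-artifact epochs of ``state``.

    Returns ``(per_epoch, mean)``; ``per_epoch`` is NaN outside the selected
    state or on artifact epochs.  The mean is NaN when no epoch qualifies.
    """
    if isinstance(band, str):
        band = (bands or default_bands())[band]
    per_epoch = np.nansum(spectra.power[:, band.mask(spectra.freqs)], axis=1)
    per_epoch[spectra.artifact] = np.nan
    if state is not None:
        per_epoch = np.where(spectra.states == state, per_epoch, np.nan)
    good = ~np.isnan(per_epoch)
    mean = float(np.mean(per_epoch[good])) if good.any() else math.nan
    return per_epoch, mean


def theta_beta_ratio(spectra: EpochSpectra, state: str = WAKE,
                     bands: dict[str, Band] | None = None) -> float:
    """Mean total-theta power over mean beta power across epochs of ``state``."""
    bands = bands or default_bands()
    _, theta = band_power(spectra, bands["theta_total"], state)
    _, beta = band_power(spectra, bands["beta"], state)
    if not beta or math.isnan(beta) or math.isnan(theta):
        return math.nan
    return theta / beta


def swa_timecourse(spectra: EpochSpectra, hyp: Hypnogram, bin_h: float = 1.0,
                   band: str = "swa") -> np.ndarray:
    """Mean NREM band power per time bin (default hourly SWA).

    Bins align to recording start (lights-on).  Bins without any usable NREM
    epoch are NaN.
    """
    per_epoch, _ = band_power(spectra, band, NREM)
    epochs_per_bin = bin_h * 3600.0 / hyp.epoch_s
    bins = np.floor(np.arange(spectra.n_epochs) / epochs_per_bin).astype(int)
    out = np.full(bins.max() + 1, np.nan)
    for b in range(out.size):
        vals = per_epoch[bins == b]
        good = ~np.isnan(vals)
        if good.any():
            out[b] = float(np.mean(vals[good]))
    return out


def swa_change(timecourse: np.ndarray, phase: str = "light",
               bins_per_phase: int = 12) -> float:
    """First-hour minus twelfth-hour mean SWA within the light or dark phase."""
    off = 0 if phase == "light" else bins_per_phase
    first, last = off, off + bins_per_phase - 1
    if last >= len(timecourse) or math.isnan(timecourse[first]) or math.isnan(timecourse[last]):
        return math.nan
    return float(timecourse[first] - timecourse[last])


def sigma_change(timecourse: np.ndarray, bins_per_phase: int = 12) -> float:
    """Twelfth-hour minus first-hour mean (light period): the sign convention
    for sigma power, which rises as sleep pressure dissipates."""
    return -swa_change(timecourse, phase="light", bins_per_phase=bins_per_phase)


# ---------------------------------------------------------------------------
# EMG power and quiet/active wake classification
# ---------------------------------------------------------------------------

@dataclass
class WakeClassification:
    """Quiet/active wake split from EMG epoch power.

    ``labels`` holds 'quiet'/'active' for wake epochs and '' elsewhere;
    ``threshold`` is the 95th percentile (linear interpolation) of NREM-epoch
    EMG power.
    """
    threshold: float
    labels: np.ndarray
    percent_quiet: dict[str, float] = field(default_factory=dict)


def emg_epoch_power(rec: PSGRecording, hyp: Hypnogram, channel: str = "EMG",
                    highpass_hz: float | None = 10.0) -> np.ndarray:
    """Mean squared EMG amplitude per epoch (µV²), after 10 Hz high-pass.

    The high-pass mirrors the EMG acquisition band (10–500 Hz); pass
    ``highpass_hz=None`` for signals already conditioned.
    """
    x = rec.channel(channel)
    if highpass_hz is not None and highpass_hz > 0:
        sos = sps.butter(2, highpass_hz, btype="highpass", fs=rec.fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    spe = int(round(hyp.epoch_s * rec.fs))
    n_ep = min(hyp.n_epochs, len(x) // spe)
    if n_ep < hyp.n_epochs:
        raise ValueError("hypnogram longer than recording")
    seg = x[: n_ep * spe].reshape(n_ep, spe)
    return np.mean(seg ** 2, axis=1)


def classify_wake(emg_power: np.ndarray, hyp: Hypnogram,
                  percentile: float = 95.0, light_h: float = 12.0) -> WakeClassification:
    """Split wake epochs into quiet/active by the NREM EMG-power threshold.

    The threshold is the ``percentile``-th percentile (linear interpolation
    between order statistics) of EMG power over all NREM epochs; wake epochs
    strictly above it are active, at/below are quiet.  Percent quiet wake is
    reported per light/dark phase relative to total wake in that phase.
    """
    emg_power = np.asarray(emg_power, dtype=float)
    if emg_power.size != hyp.n_epochs:
        raise ValueError("emg_power and hypnogram length mismatch")
    nrem = emg_power[hyp.labels == NREM]
    if nrem.size == 0:
        raise ValueError("no NREM epochs: quiet/active threshold undefined")
    threshold = float(np.percentile(nrem, percentile))

    labels = np.full(hyp.n_epochs, "", dtype="<U6")
    wake = hyp.labels == WAKE
    labels[wake & (emg_power > threshold)] = "active"
    labels[wake & (emg_power <= threshold)] = "quiet"

    phases = phase_of_epoch(hyp, light_h=light_h)
    percent_quiet = {}
    for ph in ("light", "dark"):
        w = wake & (phases == ph)
        percent_quiet[ph] = (
            100.0 * np.sum(labels[w] == "quiet") / w.sum() if w.any() else math.nan
        )
    return WakeClassification(threshold=threshold, labels=labels,
                              percent_quiet=percent_quiet)


def band_summary(spectra: EpochSpectra, bands: dict[str, Band] | None = None) -> pd.DataFrame:
    """Tidy per-state mean band powers: columns (channel, state, band, power)."""
    bands = bands or default_bands()
    rows = []
    for state in ("W", "N", "R"):
        for name, band in bands.items():
            _, mean = band_power(spectra, band, state)
            rows.append({"channel": spectra.channel, "state": state,
                         "band": name, "power": mean})
    return pd.DataFrame(rows)
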