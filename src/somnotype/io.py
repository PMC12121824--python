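"""Containers and IO for polysomnographic recordings and hypnograms.

Conventions: all signals are in µV; time is in seconds from recording start;
lights-on is at t=0 unless stated otherwise in ``lights_on_times``.  Sample
indices are 0-based with half-open intervals; epoch indices are 0-based.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Vigilance-state codes used throughout the package.
WAKE = "W"
NREM = "N"
REM = "R"
STATES = (WAKE, NREM, REM)

_LABEL_ALIASES = {
    "W": WAKE, "WAKE": WAKE, "AW": WAKE, "QW": WAKE,
    "N": NREM, "NREM": NREM, "NR": NREM, "S": NREM,
    "R": REM, "REM": REM,
}


class HypnogramError(ValueError):
    """Raised for malformed or inconsistent hypnograms."""


@dataclass
class Hypnogram:
    """Scored vigilance states at fixed epoch resolution.

    Parameters
    ----------
    labels : array of str
        One state code per epoch, drawn from {'W', 'N', 'R'}.
    epoch_s : float
        Epoch length in seconds (4 s by scoring convention).
    artifact : array of bool, optional
        Per-epoch artifact flags; artifact epochs keep their state label but
        are excluded from spectral and event analyses.
    """

    labels: np.ndarray
    epoch_s: float = 4.0
    artifact: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.size == 0:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if self.epoch_s <= 0:
            raise HypnogramError(f"epoch_s must be positive, got {self.epoch_s}")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise HypnogramError(f"unknown state labels: {sorted(bad)}")
        if self.artifact is None:
            self.artifact = np.zeros(self.labels.size, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.artifact.size != self.labels.size:
            raise HypnogramError(
                f"artifact flags ({self.artifact.size}) and labels "
                f"({self.labels.size}) differ in length"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration(self) -> float:
        """Total scored time in seconds."""
        return self.n_epochs * self.epoch_s

    def epoch_times(self) -> np.ndarray:
        """Start time of each epoch in seconds."""
        return np.arange(self.n_epochs) * self.epoch_s

    def __len__(self) -> int:
        return self.n_epochs

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.epoch_s == other.epoch_s
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.artifact, other.artifact)
        )


@dataclass
class PSGRecording:
    """Multichannel polysomnographic signal container.

    channels maps a label (e.g. ``"EEG Frontal"``) to a 1-D float array in µV.
    ``lights_on_times`` holds lights-on clock times in seconds from recording
    start; the default single entry 0.0 encodes the lights-on-at-start
    convention of the synthetic generator.
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_time: str = "00.00.00"
    lights_on_times: list[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise KeyError(
                f"channel {label!r} not in recording (have {sorted(self.channels)})"
            )
        return self.channels[label]


# ---------------------------------------------------------------------------
# EDF IO
# ---------------------------------------------------------------------------

def read_edf(path, resample_to: float | None = None) -> PSGRecording:
    """Read a continuous EDF/EDF+ recording into a :class:`PSGRecording`.

    Channel data are converted to µV using the EDF physical-dimension fields.
    If channels carry different sampling rates they are only resampled onto a
    common rate when ``resample_to`` is given; otherwise a mixed-rate file is
    an error.
    """
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise OSError(f"empty or missing EDF file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if resample_to is not None:
        raw = raw.resample(resample_to, verbose="error")
    fs = float(raw.info["sfreq"])
    # get_data(units=...) uses the recorded physical dimension; channels with
    # no dimension are assumed to be µV already (warned by mne at read time).
    try:
        data = raw.get_data(units="uV")
    except ValueError:
        warnings.warn("EDF channel without physical dimension; assuming µV")
        data = raw.get_data() * 1e6
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    start = raw.info["meas_date"]
    start_str = start.strftime("%H.%M.%S") if start is not None else "00.00.00"
    return PSGRecording(channels=channels, fs=fs, start_time=start_str)


def write_edf(rec: PSGRecording, path) -> None:
    """Write a recording to EDF (16-bit); see :mod:`somnotype.edf`."""
    from .edf import write_edf as _write
    _write(rec, path)


# ---------------------------------------------------------------------------
# Hypnogram IO
# ---------------------------------------------------------------------------

def _parse_label(token: str, row: int) -> str:
    key = token.strip().upper()
    if key not in _LABEL_ALIASES:
        raise HypnogramError(f"unknown state token {token!r} at row {row}")
    return _LABEL_ALIASES[key]


def read_hypnogram(path, epoch_s: float = 4.0) -> Hypnogram:
    """Read a hypnogram from CSV (epoch_index,state,artifact) or a compact
    single-line string of state codes (e.g. ``"WWNNR"``).

    The CSV dialect has one row per epoch; a header row is optional.  The
    artifact column is optional and defaults to 0.
    """
    text = Path(path).read_text().strip()
    if not text:
        raise HypnogramError(f"empty hypnogram file: {path}")
    lines = text.splitlines()
    if len(lines) == 1 and "," not in lines[0]:
        labels = [_parse_label(c, i) for i, c in enumerate(lines[0].strip())]
        return Hypnogram(np.array(labels), epoch_s=epoch_s)

    labels, artifact = [], []
    reader = csv.reader(lines)
    for i, row in enumerate(reader):
        if not row or not row[0].strip():
            continue
        if i == 0 and not row[0].strip().lstrip("-").isdigit():
            continue  # header row
        if len(row) < 2:
            raise HypnogramError(f"row {i}: expected at least epoch_index,state")
        labels.append(_parse_label(row[1], i))
        flag = row[2].strip() if len(row) > 2 else "0"
        artifact.append(flag in ("1", "true", "True"))
    if not labels:
        raise HypnogramError(f"no epochs found in {path}")
    return Hypnogram(np.array(labels), epoch_s=epoch_s, artifact=np.array(artifact))


def write_hypnogram(hyp: Hypnogram, path) -> None:
    """Write a hypnogram in the CSV dialect read by :func:`read_hypnogram`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "state", "artifact"])
        for i, (lab, art) in enumerate(zip(hyp.labels.tolist(), hyp.artifact.tolist())):
            w.writerow([i, lab, int(art)])


# ---------------------------------------------------------------------------
# Epoch/sample alignment
# ---------------------------------------------------------------------------

def epoch_slices(rec: PSGRecording, hyp: Hypnogram) -> list[tuple[int, int]]:
    """Half-open sample intervals for each hypnogram epoch.

    Epoch i covers samples [i*epoch_s*fs, (i+1)*epoch_s*fs).  The number of
    samples per epoch must be integral; the hypnogram must not outrun the
    recording (a trailing unscored partial epoch of signal is tolerated with
    a warning).
    """
    spe = hyp.epoch_s * rec.fs
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(
            f"epoch_s*fs = {spe} is not an integer number of samples"
        )
    spe = int(round(spe))
    needed = hyp.n_epochs * spe
    if needed > rec.n_samples:
        raise ValueError(
            f"hypnogram ({needed} samples) longer than recording ({rec.n_samples})"
        )
    if rec.n_samples - needed >= 1 and rec.n_samples % spe:
        warnings.warn("recording has a trailing partial epoch beyond the hypnogram")
    return [(i * spe, (i + 1) * spe) for i in range(hyp.n_epochs)]


def state_sample_mask(rec: PSGRecording, hyp: Hypnogram, state: str,
                      exclude_artifact: bool = True) -> np.ndarray:
    """Boolean per-sample mask of epochs labelled ``state``."""
    spe = int(round(hyp.epoch_s * rec.fs))
    sel = hyp.labels == state
    if exclude_artifact:
        sel = sel & ~hyp.artifact
    mask = np.zeros(rec.n_samples, dtype=bool)
    mask[: hyp.n_epochs * spe] = np.repeat(sel, spe)
    return mask
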