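"""Minimal EDF (European Data Format) writer.

Writes continuous 16-bit EDF files with one-second data records and per-channel
physical scaling in µV.  The layout follows the published EDF field table:
a 256-byte fixed header, 256 bytes per signal, then little-endian int16 data
records.  Reading is delegated to mne (:func:`somnotype.io.read_edf`); this
writer exists because the pipeline must round-trip synthetic recordings and
mne's EDF export backend is an optional dependency not required here.
"""

from __future__ import annotations

import warnings
from datetime import datetime

import numpy as np


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec, path, patient_id: str = "X", recording_id: str = "X") -> None:
    """Write a :class:`~somnotype.io.PSGRecording` to ``path`` as EDF.

    The recording is truncated to a whole number of one-second data records
    (with a warning) because EDF records must tile the file exactly.
    Amplitude resolution is (phys_max - phys_min)/65535 per channel.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    labels = list(rec.channels)
    n_sig = len(labels)
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_records * fs != rec.n_samples:
        warnings.warn("truncating recording to a whole number of 1-s EDF records")

    phys_min, phys_max, scaled = [], [], []
    dig_min, dig_max = -32768, 32767
    for lab in labels:
        x = rec.channels[lab][: n_records * fs]
        lo = float(np.floor(min(x.min(), -1.0)))
        hi = float(np.ceil(max(x.max(), 1.0)))
        gain = (dig_max - dig_min) / (hi - lo)
        d = np.round((x - lo) * gain + dig_min).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(d)

    now = datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(rec.start_time.replace(":", "."), 8),
        _field(256 * (1 + n_sig), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),          # record duration, seconds
        _field(n_sig, 4),
    ])
    sig_header = b"".join([
        b"".join(_field(lab, 16) for lab in labels),
        b"".join(_field("", 80) for _ in labels),          # transducer
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(f"{phys_min[i]:g}", 8) for i in range(n_sig)),
        b"".join(_field(f"{phys_max[i]:g}", 8) for i in range(n_sig)),
        b"".join(_field(dig_min, 8) for _ in labels),
        b"".join(_field(dig_max, 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),          # prefiltering
        b"".join(_field(fs, 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for d in scaled:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())
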