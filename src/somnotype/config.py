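"""Analysis configuration: every threshold of the pipeline in one file.

Defaults are the standard settings used throughout the package (4-s epochs,
8-s episode rule, 20-s sleep-attempt rule, 16-s brief-awakening rule, 20-s
NREM-latency rule, the band scheme, the 95th-percentile EMG threshold and the
slow-wave/spindle criteria).  A YAML config may override any of them; the
pipeline records a hash of the effective configuration in its provenance
block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .events import SpindleCriteria, SWCriteria
from .spectral import Band


def _default_band_edges() -> dict[str, list]:
    return {
        "swa": [0.5, 4.0, True, True],
        "low_theta": [5.0, 8.0, True, False],
        "high_theta": [8.0, 12.0, True, True],
        "theta_total": [5.0, 12.0, True, True],
        "sigma": [12.0, 15.0, False, True],
        "beta": [15.0, 30.0, False, True],
    }


@dataclass
class AnalysisConfig:
    epoch_s: float = 4.0
    light_h: float = 12.0                 # light-phase length, 12h:12h schedule
    eeg_channels: list[str] = field(default_factory=lambda: ["EEG Frontal", "EEG Parietal"])
    emg_channel: str = "EMG"
    #: per-channel bands flagged invalid (e.g. a mis-set acquisition filter);
    #: maps channel -> list of band names excluded from reports
    invalid_bands: dict[str, list[str]] = field(default_factory=dict)
    episode_min_s: float = 8.0
    attempt_sleep_max_s: float = 20.0
    attempt_wake_min_s: float = 20.0
    brief_awakening_max_s: float = 16.0
    nrem_latency_min_s: float = 20.0
    emg_percentile: float = 95.0
    swa_bin_h: float = 1.0
    sleep_window_span_h: float = 3.0
    bands: dict[str, list] = field(default_factory=_default_band_edges)
    slow_waves: dict = field(default_factory=lambda: asdict(SWCriteria()))
    spindles: dict = field(default_factory=lambda: asdict(SpindleCriteria()))

    def __post_init__(self):
        # normalise tuples to lists so that YAML round-trips compare equal
        self.slow_waves = {k: list(v) if isinstance(v, (list, tuple)) else v
                           for k, v in self.slow_waves.items()}
        self.spindles = {k: list(v) if isinstance(v, (list, tuple)) else v
                         for k, v in self.spindles.items()}
        self.bands = {k: list(v) for k, v in self.bands.items()}

    def band_objects(self) -> dict[str, Band]:
        return {k: Band(v[0], v[1], bool(v[2]), bool(v[3]))
                for k, v in self.bands.items()}

    def sw_criteria(self) -> SWCriteria:
        d = {k: tuple(v) if isinstance(v, (list, tuple)) else v
             for k, v in self.slow_waves.items()}
        return SWCriteria(**d)

    def spindle_criteria(self) -> SpindleCriteria:
        d = {k: tuple(v) if isinstance(v, (list, tuple)) else v
             for k, v in self.spindles.items()}
        return SpindleCriteria(**d)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
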