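"""Cohort profiles parameterizing the synthetic polysomnography generator.

A :class:`CohortProfile` bundles the group-level targets a simulated cohort
should reproduce: 24-h state budgets, bout durations, dark-phase wake bias,
slow-wave and spindle rates and amplitudes, state-dependent EMG tone, and the
quiet-wake fraction.  Two profiles ship with the package:

* ``wistar_like`` — outbred control phenotype: 683.8 / 612.3 / 143.8 min in
  wake / NREM / REM per 24 h, 37.90% quiet wake in the light phase, spindles
  centred at 14.0 Hz.
* ``msp_like`` — alcohol-preferring phenotype: more wake (726.6 min), less
  NREM (566.2 min), more fragmentation, 61.44% quiet wake in the light phase,
  slower (13.3 Hz), sparser and smaller spindles, smaller slow waves with a
  blunted early-to-late rate decline.

Profiles are stored as editable YAML under ``somnotype/data`` and validated
on load.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import yaml

from .io import STATES

MINUTES_PER_DAY = 1440.0


class ProfileError(ValueError):
    """Raised when a cohort profile violates its invariants."""


@dataclass
class CohortProfile:
    name: str
    #: minutes per state per 24 h; must sum to 1440 ± 1
    target_state_minutes: dict[str, float]
    #: mean bout duration per state, seconds (geometric bout lengths)
    mean_episode_duration: dict[str, float]
    #: multiplier on wake prevalence during the dark phase (nocturnal > 1)
    dark_wake_bias: float
    #: slow waves per NREM minute at the start / end of the light period
    sw_rate_early: float
    sw_rate_late: float
    #: mean negative-peak amplitude of planted slow waves, µV
    sw_amp_mean: float
    #: spindles per NREM minute
    spindle_rate: float
    #: mean spindle centre frequency, Hz (12–18)
    spindle_freq_mean: float
    #: mean spindle envelope peak amplitude, µV
    spindle_amp_mean: float
    #: EMG RMS per behavioural state, µV
    emg_rms: dict[str, float]
    #: fraction of wake epochs that are quiet wake, per phase
    quiet_wake_fraction_light: float
    quiet_wake_fraction_dark: float = 0.2

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        total = sum(self.target_state_minutes.get(s, 0.0) for s in STATES)
        if abs(total - MINUTES_PER_DAY) > 1.0:
            raise ProfileError(
                f"target_state_minutes sum to {total:.1f}, expected 1440 ± 1"
            )
        for s in STATES:
            if self.mean_episode_duration.get(s, 0.0) <= 0:
                raise ProfileError(f"mean_episode_duration[{s}] must be positive")
        positives = {
            "dark_wake_bias": self.dark_wake_bias,
            "sw_rate_early": self.sw_rate_early,
            "sw_rate_late": self.sw_rate_late,
            "sw_amp_mean": self.sw_amp_mean,
            "spindle_rate": self.spindle_rate,
            "spindle_amp_mean": self.spindle_amp_mean,
            **{f"emg_rms[{k}]": v for k, v in self.emg_rms.items()},
        }
        for k, v in positives.items():
            if v <= 0:
                raise ProfileError(f"{k} must be strictly positive, got {v}")
        if not 12.0 <= self.spindle_freq_mean <= 18.0:
            raise ProfileError(
                f"spindle_freq_mean {self.spindle_freq_mean} outside 12–18 Hz"
            )
        for k in ("active_wake", "quiet_wake", "NREM", "REM"):
            if k not in self.emg_rms:
                raise ProfileError(f"emg_rms missing state {k!r}")
        for frac in (self.quiet_wake_fraction_light, self.quiet_wake_fraction_dark):
            if not 0.0 <= frac <= 1.0:
                raise ProfileError("quiet wake fractions must lie in [0, 1]")

    def state_fractions(self) -> dict[str, float]:
        total = sum(self.target_state_minutes[s] for s in STATES)
        return {s: self.target_state_minutes[s] / total for s in STATES}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortProfile":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _load_shipped(name: str) -> CohortProfile:
    text = resources.files("somnotype.data").joinpath(f"{name}.yaml").read_text()
    return CohortProfile(**yaml.safe_load(text))


def wistar_like() -> CohortProfile:
    """Outbred-control cohort profile."""
    return _load_shipped("wistar")


def msp_like() -> CohortProfile:
    """Alcohol-preferring cohort profile (fragmented, spindle-poor)."""
    return _load_shipped("msp")
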