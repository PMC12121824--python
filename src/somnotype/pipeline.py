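"""End-to-end per-animal and per-cohort phenotyping.

``run_pipeline`` executes IO → architecture → spectral → events in order and
assembles a :class:`PhenotypeReport` mirroring the full panel set of a sleep
phenotyping study: state budgets and fragmentation, per-state band powers per
channel, quiet/active wake split, SWA and sigma time courses with change
scores, and early/late slow-wave and spindle summaries.  ``run_cohort`` maps
it over a manifest and reduces to group mean ± SD tables (no hypothesis
tests).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import compute_metrics
from .config import AnalysisConfig
from .events import (detect_slow_waves, detect_spindles, events_table,
                     sleep_windows, spindle_summary, sw_summary)
from .io import Hypnogram, PSGRecording, read_edf, read_hypnogram
from .spectral import (band_power, classify_wake, emg_epoch_power, epoch_psd,
                       sigma_change, swa_change, swa_timecourse,
                       theta_beta_ratio)

log = logging.getLogger("somnotype")


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name and input context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {context}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PhenotypeReport:
    """Per-animal phenotype: every panel either populated or NaN-marked."""
    animal_id: str
    architecture: dict
    band_powers: dict          # channel -> state -> band -> µV²
    theta_beta_ratio: dict     # channel -> value (wake epochs)
    wake_classification: dict  # threshold, percent quiet per phase
    swa_timecourse: dict       # channel -> hourly NREM SWA (µV²)
    swa_change: dict           # channel -> {light, dark}
    sigma_timecourse: dict
    sigma_change: dict         # channel -> value (light period)
    slow_waves: dict           # channel -> window -> summary
    spindles: dict             # channel -> window -> summary
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def clean(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            if isinstance(o, np.ndarray):
                return [clean(v) for v in o.tolist()]
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return clean(float(o))
            return o
        Path(path).write_text(json.dumps(clean(asdict(self)), indent=1))


def _load_inputs(recording, hypnogram, config: AnalysisConfig
                 ) -> tuple[PSGRecording, Hypnogram]:
    rec = recording if isinstance(recording, PSGRecording) else read_edf(recording)
    hyp = hypnogram if isinstance(hypnogram, Hypnogram) else read_hypnogram(
        hypnogram, epoch_s=config.epoch_s)
    spe = hyp.epoch_s * rec.fs
    if hyp.n_epochs * spe > rec.n_samples + spe:  # tolerate one partial epoch
        raise ValueError(
            f"hypnogram ({hyp.duration:.0f}s) and recording "
            f"({rec.duration:.0f}s) differ by more than one epoch"
        )
    return rec, hyp


def run_pipeline(recording, hypnogram, config: AnalysisConfig | None = None,
                 animal_id: str = "animal", out_dir=None) -> PhenotypeReport:
    """Full single-animal analysis.

    ``recording``/``hypnogram`` may be paths (EDF / hypnogram CSV) or
    in-memory :class:`PSGRecording` / :class:`Hypnogram` objects.  When
    ``out_dir`` is given, writes ``<id>_report.json`` plus tidy CSV event
    tables.  Deterministic for fixed inputs and config.
    """
    cfg = config or AnalysisConfig()
    bands = cfg.band_objects()

    try:
        rec, hyp = _load_inputs(recording, hypnogram, cfg)
    except Exception as e:
        raise PipelineError("psg_io", f"{recording!r}/{hypnogram!r}", e) from e
    log.info("io: %d epochs, %d artifact-flagged, fs=%g Hz",
             hyp.n_epochs, int(hyp.artifact.sum()), rec.fs)

    try:
        arch = compute_metrics(hyp, light_h=cfg.light_h).to_dict()
    except Exception as e:
        raise PipelineError("architecture", animal_id, e) from e

    band_powers: dict = {}
    tbr: dict = {}
    swa_tc: dict = {}
    swa_ch: dict = {}
    sig_tc: dict = {}
    sig_ch: dict = {}
    sw_out: dict = {}
    sp_out: dict = {}
    event_frames = []
    try:
        windows = sleep_windows(hyp, light_h=cfg.light_h,
                                span_h=cfg.sleep_window_span_h)
        for ch in cfg.eeg_channels:
            if ch not in rec.channels:
                continue
            spectra = epoch_psd(rec, hyp, ch)
            bad = set(cfg.invalid_bands.get(ch, []))
            band_powers[ch] = {
                state: {name: (band_power(spectra, b, state)[1]
                               if name not in bad else math.nan)
                        for name, b in bands.items()}
                for state in ("W", "N", "R")
            }
            tbr[ch] = theta_beta_ratio(spectra, bands=bands)
            tc = swa_timecourse(spectra, hyp, bin_h=cfg.swa_bin_h)
            swa_tc[ch] = tc
            swa_ch[ch] = {ph: swa_change(tc, phase=ph) for ph in ("light", "dark")}
            stc = swa_timecourse(spectra, hyp, bin_h=cfg.swa_bin_h, band="sigma")
            sig_tc[ch] = stc
            sig_ch[ch] = sigma_change(stc)

            sw_out[ch], sp_out[ch] = {}, {}
            for wname, win in windows.items():
                if win.n_epochs == 0:
                    sw_out[ch][wname] = sw_summary([], win, hyp.epoch_s)
                    sp_out[ch][wname] = spindle_summary([], win, hyp.epoch_s)
                    continue
                sw = detect_slow_waves(rec, hyp, win, channel=ch,
                                       criteria=cfg.sw_criteria())
                sp = detect_spindles(rec, hyp, win, channel=ch,
                                     criteria=cfg.spindle_criteria())
                log.info("events[%s/%s]: %d slow waves, %d spindles",
                         ch, wname, len(sw), len(sp))
                sw_out[ch][wname] = sw_summary(sw, win, hyp.epoch_s)
                sp_out[ch][wname] = spindle_summary(sp, win, hyp.epoch_s)
                for kind, evs in (("slow_wave", sw), ("spindle", sp)):
                    df = events_table(evs)
                    if not df.empty:
                        df.insert(0, "window", wname)
                        df.insert(0, "channel", ch)
                        df.insert(0, "kind", kind)
                        event_frames.append(df)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("spectral/events", animal_id, e) from e

    try:
        emg_pow = emg_epoch_power(rec, hyp, channel=cfg.emg_channel)
        wc = classify_wake(emg_pow, hyp, percentile=cfg.emg_percentile,
                           light_h=cfg.light_h)
        wake_cls = {"threshold_uv2": wc.threshold,
                    "percent_quiet": wc.percent_quiet}
    except Exception as e:
        raise PipelineError("motor_activity", animal_id, e) from e

    report = PhenotypeReport(
        animal_id=animal_id,
        architecture=arch,
        band_powers=band_powers,
        theta_beta_ratio=tbr,
        wake_classification=wake_cls,
        swa_timecourse={k: v.tolist() for k, v in swa_tc.items()},
        swa_change=swa_ch,
        sigma_timecourse={k: v.tolist() for k, v in sig_tc.items()},
        sigma_change=sig_ch,
        slow_waves=sw_out,
        spindles=sp_out,
        provenance={"config_hash": cfg.hash(), "software_version": __version__},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / f"{animal_id}_report.json")
        if event_frames:
            pd.concat(event_frames, ignore_index=True).to_csv(
                out / f"{animal_id}_events.csv", index=False)
        report_rows(report).to_csv(out / f"{animal_id}_metrics.csv", index=False)
    return report


def report_rows(report: PhenotypeReport) -> pd.DataFrame:
    """Flatten a report into a tidy (animal, metric, value) long table."""
    rows: list[dict] = []

    def emit(metric: str, value, **keys):
        if isinstance(value, (int, float, np.floating)) and value is not None:
            rows.append({"animal_id": report.animal_id, "metric": metric,
                         "value": float(value), **keys})

    for s, v in report.architecture["minutes_per_state"].items():
        emit("minutes", v, state=s, phase="24h")
    for ph, d in report.architecture["minutes_per_state_phase"].items():
        for s, v in d.items():
            emit("minutes", v, state=s, phase=ph)
    for ph, d in report.architecture["episode_counts"].items():
        for s, v in d.items():
            emit("episode_count", v, state=s, phase=ph)
    for s, v in report.architecture["mean_bout_duration"].items():
        emit("mean_bout_duration_s", v, state=s)
    for pair, v in report.architecture["transitions"].items():
        emit("transitions", v, pair=pair)
    emit("sleep_attempts", report.architecture["sleep_attempts"])
    emit("brief_awakenings", report.architecture["brief_awakenings"])
    emit("nrem_latency_s", report.architecture["nrem_latency_s"])
    emit("fragmentation_index", report.architecture["fragmentation_index"])
    for ch, states in report.band_powers.items():
        for s, bandvals in states.items():
            for b, v in bandvals.items():
                emit("band_power", v, channel=ch, state=s, band=b)
    for ch, v in report.theta_beta_ratio.items():
        emit("theta_beta_ratio", v, channel=ch)
    emit("emg_threshold_uv2", report.wake_classification["threshold_uv2"])
    for ph, v in report.wake_classification["percent_quiet"].items():
        emit("percent_quiet_wake", v, phase=ph)
    for ch, d in report.swa_change.items():
        for ph, v in d.items():
            emit("swa_change", v, channel=ch, phase=ph)
    for ch, v in report.sigma_change.items():
        emit("sigma_change", v, channel=ch)
    for name, block in (("sw", report.slow_waves), ("spindle", report.spindles)):
        for ch, wins in block.items():
            for wname, summ in wins.items():
                for k, v in summ.items():
                    emit(f"{name}_{k}", v, channel=ch, window=wname)
    return pd.DataFrame(rows)


def run_cohort(manifest, config: AnalysisConfig | None = None,
               out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline over a manifest of animals.

    ``manifest`` is a CSV path or DataFrame with columns
    (animal_id, edf_path, hypnogram_path, group).  Returns the tidy
    per-animal long table and the group mean ± SD summary.
    """
    cfg = config or AnalysisConfig()
    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    required = {"animal_id", "edf_path", "hypnogram_path", "group"}
    if df.empty:
        raise ValueError("empty cohort manifest")
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    tables = []
    for row in df.itertuples(index=False):
        rep = run_pipeline(row.edf_path, row.hypnogram_path, cfg,
                           animal_id=str(row.animal_id), out_dir=out_dir)
        t = report_rows(rep)
        t["group"] = row.group
        tables.append(t)
    long = pd.concat(tables, ignore_index=True)

    keys = [c for c in ("metric", "state", "phase", "pair", "channel",
                        "band", "window") if c in long.columns]
    grouped = (long.groupby(["group"] + keys, dropna=False)["value"]
               .agg(["mean", "std", "count"]).reset_index())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        long.to_csv(out / "cohort_long.csv", index=False)
        grouped.to_csv(out / "cohort_groups.csv", index=False)
    return long, grouped
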