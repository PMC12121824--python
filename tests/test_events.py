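"""Slow-wave and spindle detectors: constructed-signal oracles and properties."""

import math

import numpy as np
import pytest

import somnotype as st
from somnotype import events as ev
from somnotype.synth import PlantedSW, PlantedSpindle, _sw_waveform, _spindle_waveform

FS = 256.0


def quiet_nrem(n_epochs=30, noise_uv=6.0, sigma_band_uv=3.0, seed=0):
    """Low-noise NREM recording for constructed-signal oracles.

    Carries a broadband floor plus a realistic sigma-band (12-18 Hz) noise
    floor, so the spindle decision signals see the background they are
    normalised against (a sigma-only background would saturate the moving
    correlation).
    """
    from scipy import signal as sps
    rng = np.random.default_rng(seed)
    n = int(n_epochs * 4 * FS)
    sig = noise_uv * rng.standard_normal(n)
    if sigma_band_uv:
        sos = sps.butter(4, [12, 18], btype="bandpass", fs=FS, output="sos")
        band = sps.sosfilt(sos, rng.standard_normal(n))
        sig += sigma_band_uv * band / np.sqrt(np.mean(band ** 2))
    hyp = st.Hypnogram(np.array(["N"] * n_epochs))
    return sig, hyp


def with_wave(sig, sw: PlantedSW):
    out = sig.copy()
    w = _sw_waveform(FS, sw)
    i0 = int(sw.start * FS)
    out[i0:i0 + w.size] += w
    return out


def with_burst(sig, sp: PlantedSpindle, seed=1):
    out = sig.copy()
    w = _spindle_waveform(FS, sp, np.random.default_rng(seed))
    i0 = int(sp.start * FS)
    out[i0:i0 + w.size] += w
    return out


def window_for(hyp):
    return ev.SleepWindow("early", np.arange(hyp.n_epochs))


class TestSlowWaveOracle:
    def test_planted_biphasic_wave_measured_correctly(self):
        sig, hyp = quiet_nrem()
        sig = with_wave(sig, PlantedSW(40.0, 75.0, 40.0, 0.3, 0.3))
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        got = ev.detect_slow_waves(rec, hyp, window_for(hyp))
        near = [e for e in got if 39.0 < e.start < 41.0]
        assert len(near) == 1
        e = near[0]
        # planted ptp 115 µV, measured on the band-passed signal (slight
        # passband droop of the zero-phase filter)
        assert 105.0 <= e.ptp <= 120.0
        assert 0.55 <= e.duration <= 0.70
        assert e.frequency == pytest.approx(1 / e.duration)
        assert e.slope == pytest.approx(e.ptp / 0.3, rel=0.2)

    def test_sub_ptp_wave_rejected(self):
        sig, hyp = quiet_nrem(noise_uv=0.5)
        sig = with_wave(sig, PlantedSW(40.0, 11.0, 10.0, 0.3, 0.3))  # ptp 21
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        got = ev.detect_slow_waves(rec, hyp, window_for(hyp))
        assert not [e for e in got if 39.5 < e.start < 41.0]

    def test_too_short_negative_deflection_rejected(self):
        sig, hyp = quiet_nrem(noise_uv=0.5)
        sig = with_wave(sig, PlantedSW(40.0, 75.0, 40.0, 0.05, 0.3))
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        got = ev.detect_slow_waves(rec, hyp, window_for(hyp))
        assert not [e for e in got if 39.8 < e.start < 40.2 and e.ptp > 60]

    def test_returned_events_satisfy_all_invariants(self, synthetic_nrem):
        rec, hyp, _ = synthetic_nrem
        for e in ev.detect_slow_waves(rec, hyp, window_for(hyp)):
            assert 0.1 <= e.mid_zero_crossing - e.start <= 2.0
            assert 0.1 <= e.end - e.mid_zero_crossing <= 2.0
            assert 10 <= e.neg_peak_amp <= 400 and 10 <= e.pos_peak_amp <= 400
            assert e.ptp >= 30 and 0.5 <= e.frequency <= 4.0
            assert e.duration == pytest.approx(e.end - e.start)

    def test_empty_window_rejected(self, synthetic_nrem):
        rec, hyp, _ = synthetic_nrem
        with pytest.raises(ValueError):
            ev.detect_slow_waves(rec, hyp, ev.SleepWindow("late", np.array([], int)))


class TestSpindleOracle:
    def test_planted_burst_measured_correctly(self):
        sig, hyp = quiet_nrem()
        # 1.0 s, 14 Hz, envelope peak ~5x the sigma-band background
        sig = with_burst(sig, PlantedSpindle(40.0, 1.0, 14.0, 15.0))
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        got = ev.detect_spindles(rec, hyp, window_for(hyp))
        near = [e for e in got if 39.5 < e.start < 41.5]
        assert len(near) == 1
        e = near[0]
        assert 13.75 <= e.mean_frequency <= 14.25
        # the detected extent of a Gaussian-envelope burst is its
        # supra-threshold body, roughly two-thirds of the nominal duration
        assert 0.55 <= e.duration <= 1.3
        assert 8 <= e.n_oscillations <= 16

    def test_short_burst_rejected(self):
        sig, hyp = quiet_nrem()
        sig = with_burst(sig, PlantedSpindle(40.0, 0.3, 14.0, 15.0))
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        got = ev.detect_spindles(rec, hyp, window_for(hyp))
        assert not [e for e in got if 39.5 < e.start < 41.0]

    def test_out_of_band_burst_rejected(self):
        sig, hyp = quiet_nrem()
        sig = with_burst(sig, PlantedSpindle(40.0, 1.0, 25.0, 15.0))
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        got = ev.detect_spindles(rec, hyp, window_for(hyp))
        assert not [e for e in got if 39.5 < e.start < 41.0]

    def test_returned_events_satisfy_all_invariants(self, synthetic_nrem):
        rec, hyp, _ = synthetic_nrem
        for e in ev.detect_spindles(rec, hyp, window_for(hyp)):
            assert 0.5 <= e.duration <= 15.0
            assert 12.0 <= e.mean_frequency <= 18.0
            assert e.n_oscillations >= 1 and e.amplitude > 0

    def test_translation_equivariance(self):
        sig, hyp = quiet_nrem(n_epochs=40)
        sig = with_burst(sig, PlantedSpindle(40.0, 1.0, 14.0, 15.0))
        shift_ep = 5
        shifted = np.roll(sig, int(shift_ep * 4 * FS))
        rec1 = st.PSGRecording({"EEG Frontal": sig}, fs=FS)
        rec2 = st.PSGRecording({"EEG Frontal": shifted}, fs=FS)
        e1 = [e for e in ev.detect_spindles(rec1, hyp, window_for(hyp))
              if 39.5 < e.start < 41.5]
        e2 = [e for e in ev.detect_spindles(rec2, hyp, window_for(hyp))
              if 39.5 + 20 < e.start < 41.5 + 20]
        assert len(e1) == len(e2) == 1
        assert abs((e2[0].start - e1[0].start) - 20.0) <= 1 / FS

    def test_window_shorter_than_moving_window_rejected(self, wistar):
        rec = st.PSGRecording({"EEG Frontal": np.zeros(int(4 * FS))}, fs=FS)
        hyp = st.Hypnogram(np.array(["N"]))
        # a single 4-s epoch is fine; build a degenerate sub-sample window
        tiny = st.PSGRecording({"EEG Frontal": np.zeros(16)}, fs=16.0)
        hyp1 = st.Hypnogram(np.array(["N"]), epoch_s=1.0)
        with pytest.raises(ValueError):
            ev.detect_spindles(tiny, hyp1, ev.SleepWindow("early", np.array([0])))


class TestSummaries:
    def test_sw_summary_arithmetic(self):
        win = ev.SleepWindow("early", np.arange(150))  # 10 NREM min
        events = [
            ev.SWEvent(0, 0.3, 0.6, 60, 40, 100, 0.6, 300, 1.67),
            ev.SWEvent(5, 5.3, 5.6, 80, 60, 140, 0.6, 400, 1.67),
        ]
        s = ev.sw_summary(events, win)
        assert s["amplitude_uv"] == pytest.approx(120.0)
        assert s["incidence_per_min"] == pytest.approx(0.2)

    def test_spindle_incidence(self):
        win = ev.SleepWindow("early", np.arange(225))  # 15 NREM min
        events = [ev.SpindleEvent(i, i + 1, 1.0, 30.0, 14.0, 12)
                  for i in range(30)]
        s = ev.spindle_summary(events, win)
        assert s["incidence_per_min"] == pytest.approx(2.0)

    def test_zero_events_incidence_zero_features_nan(self):
        win = ev.SleepWindow("late", np.arange(10))
        s = ev.sw_summary([], win)
        assert s["incidence_per_min"] == 0.0
        assert math.isnan(s["amplitude_uv"])

    def test_sw_rate_recovery(self, wistar):
        """Detected incidence tracks the planted early rate within Poisson
        tolerance on >=30 NREM minutes."""
        import copy
        p = copy.deepcopy(wistar)
        p.sw_rate_early = p.sw_rate_late = 8.0
        hyp = st.Hypnogram(np.array(["N"] * 450))
        sig, truth = st.synthesize_eeg(hyp, p, fs=128.0, seed=21)
        rec = st.PSGRecording({"EEG Frontal": sig}, fs=128.0)
        win = window_for(hyp)
        s = ev.sw_summary(ev.detect_slow_waves(rec, hyp, win), win)
        planted_per_min = len(truth.slow_waves) / 30.0
        assert abs(s["incidence_per_min"] - planted_per_min) / planted_per_min < 0.15


class TestSleepWindows:
    def test_early_late_definition(self):
        labels = np.array(["N"] * 2700 + ["W"] * 8100 + ["N"] * 10800)
        hyp = st.Hypnogram(labels)  # N in first 3 h, W until 12 h, N in dark
        w = ev.sleep_windows(hyp)
        assert w["early"].n_epochs == 2700
        assert w["late"].n_epochs == 0  # last 3 h of light are wake

    def test_artifact_epochs_excluded(self):
        art = np.zeros(2700, dtype=bool)
        art[:100] = True
        hyp = st.Hypnogram(np.array(["N"] * 2700), artifact=art)
        w = ev.sleep_windows(hyp)
        assert w["early"].n_epochs == 2600
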