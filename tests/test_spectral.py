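"""Per-epoch spectra, band powers, change scores and the EMG wake classifier."""

import math

import numpy as np
import pytest

import somnotype as st
from somnotype import spectral


def nrem_hyp(n):
    return st.Hypnogram(np.array(["N"] * n))


class TestEpochPSD:
    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        fs = 512.0
        rec = st.PSGRecording({"E": rng.standard_normal(20 * 2048) * 30}, fs=fs)
        sp = spectral.epoch_psd(rec, nrem_hyp(20), "E", fmax=None)
        total = sp.power.sum(axis=1)
        wms = spectral.windowed_mean_square(
            rec.channel("E").reshape(20, 2048))
        assert np.all(np.abs(total - wms) / wms < 0.01)

    def test_sinusoid_band_power_is_half_amplitude_squared(self):
        fs, a = 512.0, 50.0
        t = np.arange(10 * 2048) / fs
        rec = st.PSGRecording({"E": a * np.sin(2 * np.pi * 2.0 * t)}, fs=fs)
        sp = spectral.epoch_psd(rec, nrem_hyp(10), "E")
        _, swa = spectral.band_power(sp, "swa", "N")
        assert swa == pytest.approx(a ** 2 / 2, rel=0.01)

    def test_planted_frequency_localizes_to_its_bin(self):
        fs = 256.0
        t = np.arange(5 * 1024) / fs
        for f0 in (2.0, 7.25, 14.0):
            rec = st.PSGRecording({"E": np.sin(2 * np.pi * f0 * t)}, fs=fs)
            sp = spectral.epoch_psd(rec, nrem_hyp(5), "E")
            peak = sp.freqs[np.argmax(sp.power[2])]
            assert abs(peak - f0) <= 0.25

    def test_zero_signal_zero_spectra(self):
        rec = st.PSGRecording({"E": np.zeros(4 * 1024)}, fs=256.0)
        sp = spectral.epoch_psd(rec, nrem_hyp(4), "E")
        assert np.nansum(sp.power) == 0.0

    def test_artifact_epochs_carry_no_values(self):
        rng = np.random.default_rng(0)
        rec = st.PSGRecording({"E": rng.standard_normal(4 * 1024)}, fs=256.0)
        hyp = st.Hypnogram(np.array(["N"] * 4),
                           artifact=np.array([0, 1, 0, 1], dtype=bool))
        sp = spectral.epoch_psd(rec, hyp, "E")
        assert np.isnan(sp.power[1]).all() and np.isnan(sp.power[3]).all()
        assert not np.isnan(sp.power[0]).any()

    def test_artifact_flag_is_local(self):
        """Flagging one epoch never changes any other epoch's spectrum."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(6 * 1024)
        rec = st.PSGRecording({"E": x}, fs=256.0)
        base = spectral.epoch_psd(rec, nrem_hyp(6), "E").power
        art = np.zeros(6, dtype=bool)
        art[2] = True
        flagged = spectral.epoch_psd(
            rec, st.Hypnogram(np.array(["N"] * 6), artifact=art), "E").power
        keep = [0, 1, 3, 4, 5]
        assert np.array_equal(base[keep], flagged[keep])

    def test_missing_channel_rejected(self):
        rec = st.PSGRecording({"E": np.zeros(1024)}, fs=256.0)
        with pytest.raises(KeyError):
            spectral.epoch_psd(rec, nrem_hyp(1), "missing")


@pytest.fixture(scope="module")
def flat_spectra():
    rng = np.random.default_rng(7)
    fs = 128.0
    n_ep = 6000
    rec = st.PSGRecording({"E": rng.standard_normal(n_ep * 512)}, fs=fs)
    hyp = st.Hypnogram(np.array(["W"] * n_ep))
    return spectral.epoch_psd(rec, hyp, "E")


class TestBandPowers:
    def test_flat_noise_beta_swa_ratio_matches_bandwidths(self, flat_spectra):
        _, swa = spectral.band_power(flat_spectra, "swa", "W")
        _, beta = spectral.band_power(flat_spectra, "beta", "W")
        # 15 bins-Hz of flat power vs 3.5 (+ the inclusive 0.25 Hz grid edges)
        expected = 60 / 15  # 60 beta bins vs 15 swa bins
        assert beta / swa == pytest.approx(expected, rel=0.05)

    def test_flat_noise_theta_beta_ratio(self, flat_spectra):
        ratio = spectral.theta_beta_ratio(flat_spectra)
        assert ratio == pytest.approx(7.0 / 15.0, rel=0.05)

    def test_band_additivity_is_exact(self, flat_spectra):
        per_lo, _ = spectral.band_power(flat_spectra, "low_theta", "W")
        per_hi, _ = spectral.band_power(flat_spectra, "high_theta", "W")
        per_tot, _ = spectral.band_power(flat_spectra, "theta_total", "W")
        assert np.allclose(per_lo + per_hi, per_tot, equal_nan=True)

    def test_sigma_captures_14hz_sinusoid(self):
        fs = 256.0
        t = np.arange(5 * 1024) / fs
        rec = st.PSGRecording({"E": 10 * np.sin(2 * np.pi * 14.0 * t)}, fs=fs)
        sp = spectral.epoch_psd(rec, nrem_hyp(5), "E")
        _, sigma = spectral.band_power(sp, "sigma", "N")
        assert sigma >= 0.95 * np.nansum(sp.power[0])

    def test_empty_state_selection_is_nan(self, flat_spectra):
        _, mean = spectral.band_power(flat_spectra, "swa", "R")
        assert math.isnan(mean)

    def test_doubling_theta_doubles_ratio(self, flat_spectra):
        r1 = spectral.theta_beta_ratio(flat_spectra)
        boosted = spectral.EpochSpectra(
            freqs=flat_spectra.freqs,
            power=np.where(
                (flat_spectra.freqs >= 5) & (flat_spectra.freqs <= 12),
                flat_spectra.power * 2, flat_spectra.power),
            states=flat_spectra.states, artifact=flat_spectra.artifact,
            channel="E")
        assert spectral.theta_beta_ratio(boosted) == pytest.approx(2 * r1)


class TestChangeScores:
    def test_swa_change_arithmetic(self):
        tc = np.linspace(200, 80, 12)
        assert spectral.swa_change(tc, "light") == pytest.approx(120.0)

    def test_flat_course_zero_change(self):
        assert spectral.swa_change(np.full(24, 55.0), "dark") == 0.0

    def test_missing_bin_is_nan(self):
        tc = np.full(12, 10.0)
        tc[11] = np.nan
        assert math.isnan(spectral.swa_change(tc, "light"))

    def test_sigma_change_reverses_sign(self):
        tc = np.linspace(10, 25, 12)
        assert spectral.sigma_change(tc) == pytest.approx(15.0)
        assert spectral.sigma_change(tc) == -spectral.swa_change(tc, "light")

    def test_timecourse_recovers_planted_decay(self, wistar):
        """Hourly NREM SWA declines over a light period with declining
        planted slow-wave rate."""
        hyp = st.Hypnogram(np.array(["N"] * (12 * 900)))  # 12 h NREM
        sig, _ = st.synthesize_eeg(hyp, wistar, fs=128.0, seed=2)
        rec = st.PSGRecording({"E": sig}, fs=128.0)
        sp = spectral.epoch_psd(rec, hyp, "E")
        tc = spectral.swa_timecourse(sp, hyp)
        slope = np.polyfit(np.arange(12), tc[:12], 1)[0]
        assert slope < 0


class TestWakeClassifier:
    def test_threshold_matches_interpolated_percentile(self):
        powers = np.arange(1.0, 101.0)  # NREM powers 1..100
        hyp = st.Hypnogram(np.array(["N"] * 100))
        wc = spectral.classify_wake(powers, hyp)
        assert wc.threshold == pytest.approx(95.05)

    def test_labels_follow_threshold_rule_exactly(self):
        rng = np.random.default_rng(11)
        labels = np.array(["N"] * 50 + ["W"] * 50)
        powers = np.concatenate([rng.uniform(1, 10, 50), rng.uniform(5, 20, 50)])
        hyp = st.Hypnogram(labels)
        wc = spectral.classify_wake(powers, hyp)
        thr = np.percentile(powers[:50], 95)
        want = np.where(powers[50:] > thr, "active", "quiet")
        assert (wc.labels[50:] == want).all()

    def test_all_wake_below_threshold_is_all_quiet(self):
        hyp = st.Hypnogram(np.array(["N"] * 20 + ["W"] * 10))
        powers = np.array([10.0] * 20 + [1.0] * 10)
        wc = spectral.classify_wake(powers, hyp)
        assert wc.percent_quiet["light"] == 100.0

    def test_no_nrem_rejected(self):
        hyp = st.Hypnogram(np.array(["W"] * 5))
        with pytest.raises(ValueError, match="NREM"):
            spectral.classify_wake(np.ones(5), hyp)


class TestEMGPower:
    def test_constant_rms_noise_concentrates(self):
        rng = np.random.default_rng(13)
        fs = 512.0
        sigma = 8.0
        rec = st.PSGRecording({"EMG": sigma * rng.standard_normal(20 * 2048)},
                              fs=fs)
        p = spectral.emg_epoch_power(rec, nrem_hyp(20), highpass_hz=None)
        assert np.all(np.abs(p - sigma ** 2) / sigma ** 2 < 0.2)

    def test_scaling_is_quadratic(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(4 * 2048)
        rec1 = st.PSGRecording({"EMG": x}, fs=512.0)
        rec2 = st.PSGRecording({"EMG": 2 * x}, fs=512.0)
        p1 = spectral.emg_epoch_power(rec1, nrem_hyp(4), highpass_hz=None)
        p2 = spectral.emg_epoch_power(rec2, nrem_hyp(4), highpass_hz=None)
        assert np.allclose(p2, 4 * p1)

    def test_zero_signal_zero_power(self):
        rec = st.PSGRecording({"EMG": np.zeros(2 * 2048)}, fs=512.0)
        assert np.allclose(
            spectral.emg_epoch_power(rec, nrem_hyp(2), highpass_hz=None), 0.0)
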