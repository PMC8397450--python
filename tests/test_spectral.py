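"""Multitaper PSD normalization, state-locked averaging and the distance
statistic, checked against Parseval / analytic-tone / periodogram oracles."""

import numpy as np
import pytest

from betalock.core_io import (
    BANDS,
    LOW_BETA,
    PsdEstimate,
    StateIntervals,
    ValidationError,
)
from betalock.spectral import (
    band_power,
    multitaper_psd,
    psd_euclidean_distance,
    spectrogram,
    state_locked_psd,
)

from conftest import make_recording

FS = 1100.0


class TestMultitaperPsd:
    def test_zero_signal_zero_psd(self):
        psd = multitaper_psd(np.zeros(int(2 * FS)), FS)
        assert np.all(psd.power == 0.0)

    def test_white_noise_parseval(self, rng):
        x = rng.standard_normal(int(10 * FS))
        psd = multitaper_psd(x, FS)
        integral = np.trapezoid(psd.power, psd.freqs)
        assert integral == pytest.approx(np.var(x), rel=0.10)

    @pytest.mark.parametrize("amp", [1.0, 3.0])
    def test_tone_power_is_half_amplitude_squared(self, amp):
        t = np.arange(int(10 * FS)) / FS
        x = amp * np.sin(2 * np.pi * 20.0 * t)
        psd = multitaper_psd(x, FS)
        mask = (psd.freqs >= 19) & (psd.freqs <= 21)
        assert np.trapezoid(psd.power[mask], psd.freqs[mask]) == pytest.approx(
            amp**2 / 2, rel=0.10
        )

    def test_matches_averaged_periodogram_oracle(self, rng):
        """Long white noise: band power agrees with Welch within 15%."""
        from scipy.signal import welch

        x = rng.standard_normal(int(60 * FS))
        psd = multitaper_psd(x, FS)
        f_w, p_w = welch(x, FS, window="boxcar", nperseg=int(FS), noverlap=0)
        for band in BANDS.values():
            m_mt = band.mask(psd.freqs)
            m_w = band.mask(f_w)
            bp_mt = np.trapezoid(psd.power[m_mt], psd.freqs[m_mt])
            bp_w = np.trapezoid(p_w[m_w], f_w[m_w])
            assert bp_mt == pytest.approx(bp_w, rel=0.15)

    def test_short_segment_rejected_with_minimum_named(self):
        with pytest.raises(ValidationError, match="1100"):
            multitaper_psd(np.zeros(500), FS)

    def test_frequency_resolution_at_most_1hz(self):
        psd = multitaper_psd(np.zeros(int(FS)), FS)
        assert np.diff(psd.freqs)[0] <= 1.0


class TestSpectrogram:
    def test_stationary_tone_columns_equal(self):
        t = np.arange(int(6 * FS)) / FS
        rec = make_recording(np.sin(2 * np.pi * 20.0 * t), FS)
        spg = spectrogram(rec, window_len=1.0, overlap=0.5)
        ref = spg.power[:, 0]
        for k in range(1, spg.power.shape[1]):
            np.testing.assert_allclose(spg.power[:, k], ref, atol=1e-6)

    def test_column_count_framing_formula(self, rng):
        rec = make_recording(rng.standard_normal(int(10 * FS)), FS)
        spg = spectrogram(rec, window_len=1.0, overlap=0.5)
        n_win, step = int(FS), int(FS * 0.5)
        expected = (rec.n_samples - n_win) // step + 1
        assert spg.power.shape[1] == expected
        assert np.all(np.diff(spg.times) > 0)

    def test_tone_onset_detected_within_one_window(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.where(t >= 5.0, np.sin(2 * np.pi * 20.0 * t), 0.0)
        spg = spectrogram(make_recording(x, FS), window_len=1.0, overlap=0.5)
        fi = np.argmin(np.abs(spg.freqs - 20.0))
        power_20 = spg.power[fi]
        before = power_20[spg.times < 4.5]
        after = power_20[spg.times > 6.0]
        assert after.min() > 100 * max(before.max(), 1e-12)

    def test_bad_overlap_rejected(self, tone_recording):
        with pytest.raises(ValidationError):
            spectrogram(tone_recording, overlap=1.0)


class TestStateLockedPsd:
    def test_single_episode_equals_own_psd(self):
        t = np.arange(int(6 * FS)) / FS
        rec = make_recording(np.sin(2 * np.pi * 20.0 * t), FS)
        states = StateIntervals([(0.0, 6.0, "rearing")])
        locked = state_locked_psd(rec, states, "rearing")
        # 20 Hz is periodic in the 1-s window, so every window is identical
        single = multitaper_psd(rec.samples[0][: int(FS)], FS)
        np.testing.assert_allclose(locked.power, single.power, atol=1e-9)
        assert locked.meta["n_windows"] == 6

    def test_two_identical_episodes_idempotent(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 20.0 * t)
        rec = make_recording(x, FS)
        states = StateIntervals(
            [(0.0, 2.0, "rearing"), (2.0, 4.0, "inactive"), (4.0, 6.0, "rearing")]
        )
        locked = state_locked_psd(rec, states, "rearing")
        one = state_locked_psd(rec, StateIntervals([(0.0, 2.0, "rearing")]), "rearing")
        np.testing.assert_allclose(locked.power, one.power, atol=1e-9)

    def test_equal_duration_episodes_average_band_power(self):
        t = np.arange(int(6 * FS)) / FS
        amp_a, amp_b = 1.0, 3.0
        x = np.sin(2 * np.pi * 20.0 * t)
        x[: int(2 * FS)] *= amp_a
        x[int(2 * FS) : int(4 * FS)] = 0.0
        x[int(4 * FS) :] *= amp_b
        rec = make_recording(x, FS)
        states = StateIntervals(
            [(0.0, 2.0, "rearing"), (2.0, 4.0, "inactive"), (4.0, 6.0, "rearing")]
        )
        locked = state_locked_psd(rec, states, "rearing")
        ep1 = state_locked_psd(rec, StateIntervals([(0.0, 2.0, "rearing")]), "rearing")
        ep2 = state_locked_psd(rec, StateIntervals([(4.0, 6.0, "rearing")]), "rearing")
        np.testing.assert_allclose(locked.power, 0.5 * (ep1.power + ep2.power),
                                   atol=1e-9)
        # 1-s multitaper windows smear the tone over +/- 3 Hz; integrate wide
        mask = (locked.freqs >= 14) & (locked.freqs <= 26)
        bp = np.trapezoid(locked.power[mask], locked.freqs[mask])
        assert bp == pytest.approx((amp_a**2 / 2 + amp_b**2 / 2) / 2, rel=0.10)

    def test_no_qualifying_episode_raises_with_context(self, tone_recording):
        states = StateIntervals([(0.0, 10.0, "inactive")])
        with pytest.raises(ValidationError, match="rearing"):
            state_locked_psd(tone_recording, states, "rearing")


class TestBandPower:
    def test_flat_psd_relative_power_is_bandwidth_ratio(self):
        freqs = np.arange(0.0, 551.0)
        psd = PsdEstimate(freqs, np.ones_like(freqs), 5)
        rel = band_power(psd, BANDS["theta"], "relative")
        assert rel == pytest.approx(6.0 / 99.0, rel=1e-6)

    def test_dominant_tone_concentrates_relative_power(self):
        t = np.arange(int(10 * FS)) / FS
        x = 10 * np.sin(2 * np.pi * 17.0 * t)
        psd = multitaper_psd(x, FS)
        assert band_power(psd, LOW_BETA, "relative") > 0.9

    def test_zero_psd_relative_power_undefined(self):
        freqs = np.arange(0.0, 551.0)
        psd = PsdEstimate(freqs, np.zeros_like(freqs), 5)
        assert band_power(psd, LOW_BETA, "raw") == 0.0
        with pytest.raises(ValidationError, match="undefined"):
            band_power(psd, LOW_BETA, "relative")

    def test_band_outside_grid_rejected(self):
        freqs = np.arange(0.0, 20.0)
        psd = PsdEstimate(freqs, np.ones_like(freqs), 5)
        with pytest.raises(ValidationError, match="outside"):
            band_power(psd, BANDS["high_beta"], "raw")


class TestEuclideanDistance:
    def test_hand_example_three_four_vs_zero(self):
        f = np.array([20.0, 21.0])
        a = PsdEstimate(f, np.array([3.0, 4.0]), 5)
        b = PsdEstimate(f, np.array([0.0, 0.0]), 5)
        ed = psd_euclidean_distance(a, b, f_range=(13.0, 30.0))
        assert ed.value == pytest.approx(5.0)

    def test_identical_psds_zero_in_both_modes(self, rng):
        f = np.arange(10.0, 40.0)
        p = PsdEstimate(f, rng.random(f.size), 5)
        for mode in ("printed", "pointwise"):
            assert psd_euclidean_distance(p, p, mode=mode).value == pytest.approx(0.0)

    def test_antisymmetry_in_printed_mode(self, rng):
        f = np.arange(10.0, 40.0)
        a = PsdEstimate(f, rng.random(f.size), 5)
        b = PsdEstimate(f, rng.random(f.size), 5)
        ed_ab = psd_euclidean_distance(a, b).value
        ed_ba = psd_euclidean_distance(b, a).value
        assert ed_ab == pytest.approx(-ed_ba)

    def test_printed_mode_blind_to_equal_norm_spectra(self):
        f = np.arange(13.0, 31.0)
        pa = np.zeros(f.size)
        pb = np.zeros(f.size)
        pa[0], pb[-1] = 2.0, 2.0  # same norm, different shape
        a, b = PsdEstimate(f, pa, 5), PsdEstimate(f, pb, 5)
        assert psd_euclidean_distance(a, b, mode="printed").value == pytest.approx(0.0)
        assert psd_euclidean_distance(a, b, mode="pointwise").value > 0.0

    def test_scale_equivariance(self, rng):
        f = np.arange(10.0, 40.0)
        a = PsdEstimate(f, rng.random(f.size), 5)
        b = PsdEstimate(f, rng.random(f.size), 5)
        c = 7.5
        ac = PsdEstimate(f, c * a.power, 5)
        bc = PsdEstimate(f, c * b.power, 5)
        assert psd_euclidean_distance(ac, bc).value == pytest.approx(
            c * psd_euclidean_distance(a, b).value
        )

    def test_grid_mismatch_rejected(self):
        a = PsdEstimate(np.arange(10.0, 40.0), np.ones(30), 5)
        b = PsdEstimate(np.arange(10.5, 40.5), np.ones(30), 5)
        with pytest.raises(ValidationError, match="grid"):
            psd_euclidean_distance(a, b)
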