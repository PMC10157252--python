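"""Epoching, Welch band power, baseline changes, Morse wavelet transform."""

import numpy as np
import pytest
from scipy import stats as spstats

from tuspac import (
    GAMMA,
    THETA,
    TOTAL,
    BandDefinition,
    MorseParams,
    WelchParams,
    aggregate_animals,
    aggregate_trials,
    band_absolute_power,
    baseline_and_change,
    epoch_session,
    morse_tfr,
    relative_power,
    welch_psd,
)
from tuspac.synthetic import LfpSession

FS = 1000.0


def _session_with_onsets(onsets, duration, seed=0):
    rng = np.random.default_rng(seed)
    return LfpSession(
        samples=rng.standard_normal(int(duration * FS)),
        sampling_rate=FS,
        stimulus_onsets=np.asarray(onsets, dtype=float),
        state_label="awake",
    )


class TestEpoching:
    def test_segment_sample_indices(self):
        session = _session_with_onsets([20.0], 30.0)
        grid = epoch_session(session)
        # segment [0, 1) of trial 0 covers samples 20000..20999
        np.testing.assert_array_equal(
            grid.data[0, 5], session.samples[20_000:21_000]
        )
        assert grid.segment_starts_s[5] == 0

    def test_sixteen_trials_give_160_segments(self):
        onsets = 10.0 + 15.0 * np.arange(16)
        session = _session_with_onsets(onsets, 245.0)
        grid = epoch_session(session)
        assert grid.data.shape == (16, 10, 1000)

    def test_insufficient_margin_names_trial(self):
        session = _session_with_onsets([], 12.0)
        session.stimulus_onsets = np.array([4.9])  # bypass session validation
        with pytest.raises(ValueError, match="trial 0"):
            epoch_session(session)


class TestWelch:
    def test_tone_integrated_band_power(self):
        """A sqrt(2) mV tone at 8 Hz carries 1 mV^2; all of it lands in theta."""
        t = np.arange(1000) / FS
        x = np.sqrt(2) * np.cos(2 * np.pi * 8 * t)
        f, p = welch_psd(x, FS)
        df = f[1] - f[0]
        integrated = p[THETA.mask(f)].sum() * df
        assert integrated == pytest.approx(1.0, rel=0.05)

    def test_zero_signal_zero_psd(self):
        f, p = welch_psd(np.zeros(1000), FS)
        assert np.all(p == 0)

    def test_white_noise_density_level(self):
        """sigma^2 = 1 white noise has one-sided density 1/(fs/2) = 0.002."""
        means = []
        for seed in range(30):
            x = np.random.default_rng(seed).standard_normal(4000)
            f, p = welch_psd(x, FS)
            means.append(p[(f > 0) & (f < 480)].mean())
        assert np.mean(means) == pytest.approx(0.002, rel=0.10)

    def test_parseval_on_white_noise(self):
        """Integrated Welch PSD matches the segment variance within 5%."""
        ratios = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(2000)
            f, p = welch_psd(x, FS)
            ratios.append(p.sum() * (f[1] - f[0]) / np.var(x))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), FS)


class TestBandPower:
    def test_flat_psd_mean_recovered(self):
        f = np.arange(0, 501, 2.0)
        psd = np.full(f.size, 3.14)
        for band in (THETA, GAMMA, TOTAL):
            assert band_absolute_power(f, psd, band) == pytest.approx(3.14)

    def test_out_of_band_tone_excluded(self):
        t = np.arange(1000) / FS
        f, p = welch_psd(np.cos(2 * np.pi * 8 * t), FS)
        assert band_absolute_power(f, p, THETA) > 1e-3
        assert band_absolute_power(f, p, GAMMA) < 1e-8

    def test_hand_built_bins_mean(self):
        f = np.array([4.0, 6.0, 8.0, 10.0, 12.0])
        psd = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        assert band_absolute_power(f, psd, THETA) == 6.0

    def test_band_edges_inclusive(self):
        """A tone exactly at 12 Hz counts toward theta, not gamma."""
        t = np.arange(1000) / FS
        f, p = welch_psd(np.cos(2 * np.pi * 12 * t), FS)
        assert band_absolute_power(f, p, THETA) > 1e-3
        assert band_absolute_power(f, p, GAMMA) < 1e-8

    def test_empty_band_names_resolution(self):
        f = np.arange(0, 501, 2.0)
        narrow = BandDefinition("narrow", 8.5, 9.5)
        with pytest.raises(ValueError, match="resolution"):
            band_absolute_power(f, np.ones(f.size), narrow)


class TestRelativePower:
    def test_band_equals_total(self):
        assert relative_power(5.0, 5.0) == 1.0

    def test_simple_ratio(self):
        assert relative_power(2.0, 8.0) == 0.25

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_power(1.0, 0.0)

    def test_tone_relative_power_vs_direct_ratio(self):
        t = np.arange(1000) / FS
        f, p = welch_psd(np.cos(2 * np.pi * 8 * t), FS)
        ap_t = band_absolute_power(f, p, THETA)
        ap_tot = band_absolute_power(f, p, TOTAL)
        direct = p[THETA.mask(f)].mean() / p[TOTAL.mask(f)].mean()
        assert relative_power(ap_t, ap_tot) == pytest.approx(direct, rel=1e-12)


class TestBaselineChange:
    def test_worked_example(self):
        baseline, changes = baseline_and_change(
            [1, 2, 3, 4, 5, 6, 3, 3, 3, 3]
        )
        assert baseline == 3.0
        assert changes[0] == pytest.approx(1.0)
        assert np.all(changes[1:] == 0.0)

    def test_constant_series_zero_change(self):
        baseline, changes = baseline_and_change(np.full(10, 7.0))
        assert baseline == 7.0
        np.testing.assert_array_equal(changes, np.zeros(5))

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            baseline_and_change([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            baseline_and_change([1.0] * 8)


class TestAggregation:
    def test_mean_and_sem(self):
        mean, sem = aggregate_animals([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert sem == pytest.approx(1.0 / np.sqrt(3))

    def test_single_animal_sem_undefined(self):
        mean, sem = aggregate_animals([4.2])
        assert mean == 4.2
        assert np.isnan(sem)

    def test_equal_trials_mean(self):
        assert aggregate_trials([0.5] * 16) == 0.5


class TestMorse:
    def test_peak_at_tone_frequency(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        freqs, tfr = morse_tfr(x, FS)
        profile = tfr[:, 500:-500].mean(axis=1)
        peak = freqs[np.argmax(profile)]
        nearest = freqs[np.argmin(np.abs(freqs - 10.0))]
        assert peak == nearest

    def test_zero_signal_zero_tfr(self):
        freqs, tfr = morse_tfr(np.zeros(2000), FS)
        assert np.all(tfr == 0)

    def test_quadratic_in_amplitude(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 15 * t)
        _, tfr1 = morse_tfr(x, FS)
        _, tfr2 = morse_tfr(2 * x, FS)
        np.testing.assert_allclose(tfr2, 4 * tfr1, rtol=1e-9)

    def test_inadmissible_parameters_rejected(self):
        with pytest.raises(ValueError, match="inadmissible"):
            MorseParams(symmetry=3.0, time_bandwidth=2.0)

    def test_grid_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morse_tfr(np.zeros(1000), FS, MorseParams(freqs=(600.0,)))

    def test_agrees_with_welch_on_stationary_signal(self):
        """Bandwidth-normalised TFR ranks frequencies like the Welch PSD."""
        from tuspac import generate_background, morse_density_profile

        rng = np.random.default_rng(5)
        t = np.arange(20_000) / FS
        x = (
            2.0 * np.sin(2 * np.pi * 8 * t)
            + 1.0 * np.sin(2 * np.pi * 40 * t)
            + 2.0 * generate_background(20.0, FS, exponent=1.0, rng=rng)
        )
        freqs, tfr = morse_tfr(x, FS)
        density = morse_density_profile(freqs, tfr[:, 2000:-2000], FS)
        f, p = welch_psd(x, FS, WelchParams(nperseg=2000))
        sel = (freqs >= 4) & (freqs <= 100)
        welch_interp = np.interp(freqs[sel], f, p)
        rho = spstats.spearmanr(density[sel], welch_interp).statistic
        assert rho >= 0.9
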