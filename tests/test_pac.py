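"""Zero-phase filtering, Hilbert streams, and the phase-locking PAC index."""

import numpy as np
import pytest

from tuspac import (
    GAMMA,
    THETA,
    FilterSpec,
    amplitude_envelope,
    instantaneous_phase,
    pac_change,
    pac_index,
    phase_locking,
    surrogate_null,
    zero_phase_bandpass,
)
from tuspac.pac import PacEstimate

FS = 1000.0


def coupled_signal(duration, m, noise=0.0, seed=0, f_theta=8.0, f_gamma=40.0):
    """Theta tone + theta-phase-modulated gamma + optional white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * FS)) / FS
    theta = np.cos(2 * np.pi * f_theta * t)
    gamma = (1 + m * np.cos(2 * np.pi * f_theta * t)) * np.cos(
        2 * np.pi * f_gamma * t
    )
    return theta + gamma + noise * rng.standard_normal(t.size)


class TestFiltering:
    def test_passband_tone_preserved_at_zero_lag(self):
        t = np.arange(10_000) / FS
        x = np.cos(2 * np.pi * 8 * t)
        y = zero_phase_bandpass(x, FilterSpec(THETA, FS))
        core = slice(2000, -2000)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.01)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (
            y[core].size - 1
        )
        assert lag == 0

    def test_stopband_attenuation(self):
        """A 40 Hz tone through the theta band drops by >= 40 dB."""
        t = np.arange(10_000) / FS
        x = np.cos(2 * np.pi * 40 * t)
        y = zero_phase_bandpass(x, FilterSpec(THETA, FS))
        attenuation_db = -20 * np.log10(np.abs(y[2000:-2000]).max())
        assert attenuation_db >= 40

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12_000)
        spec = FilterSpec(THETA, FS)
        np.testing.assert_allclose(
            zero_phase_bandpass(x[::-1], spec),
            zero_phase_bandpass(x, spec)[::-1],
            atol=1e-9,
        )

    def test_too_short_signal_names_minimum(self):
        with pytest.raises(ValueError, match="3 x taps"):
            zero_phase_bandpass(np.zeros(100), FilterSpec(THETA, FS))

    def test_odd_tap_count(self):
        assert FilterSpec(THETA, FS).numtaps % 2 == 1
        assert FilterSpec(GAMMA, FS).numtaps % 2 == 1


class TestHilbertStreams:
    def test_phase_zero_at_cosine_peak(self):
        t = np.arange(2000) / FS
        phase = instantaneous_phase(np.cos(2 * np.pi * 8 * t))
        peaks = np.arange(0, 2000, 125)[1:-1]  # interior cosine maxima
        assert np.abs(phase[peaks]).max() < 0.02

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(2000) / FS
        pc = instantaneous_phase(np.cos(2 * np.pi * 8 * t))
        ps = instantaneous_phase(np.sin(2 * np.pi * 8 * t))
        diff = np.angle(np.exp(1j * (ps[200:-200] - pc[200:-200])))
        assert np.allclose(diff, -np.pi / 2, atol=0.02)

    def test_phase_increment_matches_frequency(self):
        t = np.arange(4000) / FS
        phase = np.unwrap(instantaneous_phase(np.cos(2 * np.pi * 8 * t)))
        increments = np.diff(phase[200:-200])
        assert increments.mean() == pytest.approx(2 * np.pi * 8 / FS, rel=0.01)

    def test_envelope_of_tone(self):
        t = np.arange(2000) / FS
        env = amplitude_envelope(np.cos(2 * np.pi * 40 * t))
        assert np.abs(env[200:-200] - 1.0).max() < 0.01

    def test_envelope_recovers_modulator(self):
        t = np.arange(4000) / FS
        modulator = 1 + 0.5 * np.cos(2 * np.pi * 8 * t)
        env = amplitude_envelope(modulator * np.cos(2 * np.pi * 40 * t))
        core = slice(400, -400)
        assert np.abs(env[core] - modulator[core]).max() < 0.05 * modulator.max()

    def test_zero_signal_zero_envelope(self):
        assert np.all(amplitude_envelope(np.zeros(1000)) == 0)


class TestPacIndex:
    def test_identical_phase_streams_give_unity(self):
        phi = np.random.default_rng(0).uniform(-np.pi, np.pi, 1000)
        assert phase_locking(phi, phi) == 1.0

    def test_clean_strong_coupling(self):
        est = pac_index(coupled_signal(10.0, m=0.9), fs=FS)
        assert est.paci >= 0.95
        assert not est.degenerate_envelope

    def test_amplitude_scaling_invariance(self):
        x = coupled_signal(10.0, m=0.5, noise=0.3, seed=1)
        a = pac_index(x, fs=FS).paci
        b = pac_index(10.0 * x, fs=FS).paci
        assert a == pytest.approx(b, abs=1e-9)

    def test_unmodulated_envelope_flagged_degenerate(self):
        est = pac_index(coupled_signal(10.0, m=0.0), fs=FS)
        assert est.degenerate_envelope

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pac_index(np.zeros(900), fs=FS, edge_trim=0.5)

    def test_monotone_in_modulation_depth(self):
        """Mean PACI strictly increases over m = 0, 0.2, ..., 0.8."""
        depths = [0.0, 0.2, 0.4, 0.6, 0.8]
        means = []
        for m in depths:
            vals = [
                pac_index(
                    coupled_signal(6.0, m=m, noise=1.0, seed=s), fs=FS
                ).paci
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_null_floor_shrinks_with_window_length(self):
        """Uncoupled PACI falls as the effective sample count grows:
        perfect negative rank correlation of the mean null index with
        window length. Phases are extracted once from a long recording
        and windowed, as the session analysis does."""
        from scipy import stats as spstats

        from tuspac import instantaneous_phase, zero_phase_bandpass, FilterSpec

        lengths = [2.0, 5.0, 10.0, 20.0]
        sums = {dur: [] for dur in lengths}
        for seed in range(12):
            x = coupled_signal(25.0, m=0.0, noise=1.0, seed=seed)
            low = zero_phase_bandpass(x, FilterSpec(THETA, FS))
            env = amplitude_envelope(zero_phase_bandpass(x, FilterSpec(GAMMA, FS)))
            env_low = zero_phase_bandpass(env - env.mean(), FilterSpec(THETA, FS))
            phi_l = instantaneous_phase(low)
            phi_h = instantaneous_phase(env_low)
            for dur in lengths:
                start = 1000  # skip the filter edge
                k = int(dur * FS)
                sums[dur].append(
                    phase_locking(phi_l[start : start + k],
                                  phi_h[start : start + k])
                )
        means = [np.mean(sums[dur]) for dur in lengths]
        rho = spstats.spearmanr(lengths, means).statistic
        assert rho == -1.0


class TestSurrogates:
    def test_coupled_signal_beats_null(self):
        x = coupled_signal(12.0, m=0.9, noise=0.5, seed=2)
        result = surrogate_null(x, fs=FS, n_surrogates=99, seed=0)
        assert result["observed"] > np.percentile(result["null"], 95)

    def test_uncoupled_percentile_not_extreme(self):
        pcts = [
            surrogate_null(
                coupled_signal(12.0, m=0.0, noise=1.0, seed=s),
                fs=FS,
                n_surrogates=49,
                seed=s,
            )["percentile"]
            for s in range(8)
        ]
        assert 5 < np.mean(pcts) < 95

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match="19"):
            surrogate_null(np.zeros(5000), fs=FS, n_surrogates=0)

    def test_too_short_for_shifts_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            surrogate_null(np.zeros(1500), fs=FS, n_surrogates=20)


class TestPacChange:
    def _estimate(self, paci):
        return PacEstimate(
            paci=paci, k=1000, phase_band=THETA, amplitude_band=GAMMA,
            edge_trim_s=0.5, window_s=(0, 2),
        )

    def test_printed_group_means_ratio(self):
        """0.025 -> 0.029 is a +16% relative change."""
        assert pac_change(
            self._estimate(0.025), self._estimate(0.029)
        ) == pytest.approx(0.16, abs=0.0001)

    def test_equal_pre_post_zero(self):
        assert pac_change(self._estimate(0.4), self._estimate(0.4)) == 0.0

    def test_decrease_is_negative(self):
        assert pac_change(self._estimate(0.037), self._estimate(0.033)) < 0

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            pac_change(self._estimate(0.0), self._estimate(0.1))
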