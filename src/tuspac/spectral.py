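"""Peristimulus spectral band-power analysis of LFP sessions.

Each stimulus is analysed in ten contiguous 1-s segments spanning [-5, 5) s
around onset (onset = t 0). Per segment, a Welch power spectral density is
estimated; absolute band power (AP) is the *mean* density over the in-band
bins (units mV^2/Hz), relative power (RP) is band AP divided by the AP of the
4-100 Hz total band, and stimulus effects are expressed as baseline-normalised
changes dAP/AP = (AP_t - AP_baseline) / AP_baseline where the baseline is the
arithmetic mean of the five pre-stimulus segments (dRP/RP analogously).

A generalized Morse wavelet transform (symmetry gamma = 3, time-bandwidth
P^2 = 60) provides the time-frequency picture of the same data.

Conventions: band edges inclusive on both ends; 0-based sample indexing;
half-open time intervals [a, b). Because AP is a mean density, RP values
across disjoint sub-bands do not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "THETA",
    "GAMMA",
    "TOTAL",
    "WelchParams",
    "MorseParams",
    "EpochGrid",
    "epoch_session",
    "welch_psd",
    "morse_tfr",
    "band_absolute_power",
    "relative_power",
    "baseline_and_change",
    "aggregate_trials",
    "aggregate_animals",
    "band_power_table",
]

N_SEGMENTS = 10
N_PRE_SEGMENTS = 5
SEGMENT_STARTS_S = tuple(range(-5, 5))  # 1-s segments [-5,-4) ... [4,5)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] Hz, endpoints inclusive."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band requires 0 < low < high, got {self}")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins inside the band (inclusive)."""
        eps = 1e-9
        return (freqs >= self.low - eps) & (freqs <= self.high + eps)


THETA = BandDefinition("theta", 4.0, 12.0)
GAMMA = BandDefinition("gamma", 30.0, 45.0)
TOTAL = BandDefinition("total", 4.0, 100.0)


@dataclass(frozen=True)
class WelchParams:
    """Welch PSD estimation settings.

    Defaults give 2 Hz resolution within a 1-s segment at fs = 1 kHz:
    Hann window of 500 samples with 50% overlap (three averaged windows).
    """

    window: str = "hann"
    nperseg: int = 500
    overlap: float = 0.5
    detrend: str = "constant"

    @property
    def noverlap(self) -> int:
        return int(round(self.nperseg * self.overlap))

    def resolution(self, fs: float) -> float:
        """Frequency bin spacing in Hz."""
        return fs / self.nperseg


DEFAULT_WELCH = WelchParams()


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet settings.

    symmetry (gamma) and time_bandwidth (P^2) parameterise the wavelet;
    the decay exponent is beta = P^2 / gamma (admissible only if beta > 1).
    """

    symmetry: float = 3.0
    time_bandwidth: float = 60.0
    freqs: tuple = tuple(np.geomspace(2.0, 100.0, 60))

    def __post_init__(self) -> None:
        if self.symmetry <= 0:
            raise ValueError("symmetry parameter must be > 0")
        if self.time_bandwidth <= self.symmetry:
            raise ValueError(
                "inadmissible Morse parameters: time_bandwidth must exceed "
                f"symmetry (beta = P^2/gamma > 1), got gamma={self.symmetry}, "
                f"P^2={self.time_bandwidth}"
            )

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.symmetry

    @property
    def peak_omega(self) -> float:
        """Peak angular frequency of the mother wavelet, (beta/gamma)^(1/gamma)."""
        return (self.beta / self.symmetry) ** (1.0 / self.symmetry)


@dataclass
class EpochGrid:
    """Trials x ten 1-s segments aligned to stimulus onset.

    data has shape (n_trials, 10, fs); segment s of trial i covers
    [onset_i + SEGMENT_STARTS_S[s], onset_i + SEGMENT_STARTS_S[s] + 1) s.
    """

    data: np.ndarray
    sampling_rate: float
    onsets: np.ndarray
    segment_starts_s: tuple = SEGMENT_STARTS_S

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]


def epoch_session(session) -> EpochGrid:
    """Slice an LFP session into per-trial peristimulus segment grids.

    Sample indices are computed by rounding onset * fs to the nearest
    integer; each trial needs >= 5 s of data on both sides of its onset.
    """
    fs = session.sampling_rate
    samples = np.asarray(session.samples)
    n = samples.size
    seg_len = int(round(fs))
    trials = []
    for i, onset in enumerate(np.asarray(session.stimulus_onsets, dtype=float)):
        onset_idx = int(round(onset * fs))
        lo = onset_idx - N_PRE_SEGMENTS * seg_len
        hi = onset_idx + (N_SEGMENTS - N_PRE_SEGMENTS) * seg_len
        if lo < 0 or hi > n:
            raise ValueError(
                f"trial {i} at {onset} s lacks the 5 s margin required on "
                f"both sides of its onset (session has {n / fs:.3f} s)"
            )
        trials.append(samples[lo:hi].reshape(N_SEGMENTS, seg_len))
    return EpochGrid(
        data=np.asarray(trials),
        sampling_rate=fs,
        onsets=np.asarray(session.stimulus_onsets, dtype=float),
    )


def welch_psd(segment, fs: float, params: WelchParams = DEFAULT_WELCH):
    """One-sided Welch PSD of a segment (or stack of segments on the last axis).

    Returns (freqs_hz, density) with density in input_units^2/Hz. Satisfies
    Parseval in expectation: sum(PSD) * df ~= variance for windowed noise.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[-1] < params.nperseg:
        raise ValueError(
            f"segment length {segment.shape[-1]} is shorter than the Welch "
            f"window ({params.nperseg} samples)"
        )
    freqs, psd = sps.welch(
        segment,
        fs=fs,
        window=params.window,
        nperseg=params.nperseg,
        noverlap=params.noverlap,
        detrend=params.detrend,
        axis=-1,
    )
    return freqs, psd


def morse_tfr(x, fs: float, params: MorseParams = MorseParams()):
    """Magnitude-squared generalized Morse wavelet transform.

    The wavelet is realised in the frequency domain,
    Psi(w) = 2 (w/w_p)^beta exp(beta/gamma - (w/w_p * w_p)^... ) -- i.e.
    a_(beta,gamma) w^beta e^(-w^gamma) for w > 0, normalised to peak value 2
    (so a unit-amplitude sinusoid yields |W| ~= 1 at its frequency). Each
    voice is the inverse FFT of the signal spectrum multiplied by the scaled
    wavelet.

    Returns (freqs_hz, tfr) with tfr of shape (n_freqs, n_samples).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    freqs = np.asarray(params.freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("Morse frequency grid must lie inside (0, fs/2)")
    beta, gam = params.beta, params.symmetry
    wp = params.peak_omega
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    X = np.fft.fft(x)
    tfr = np.empty((freqs.size, n))
    pos = omega > 0
    for j, f0 in enumerate(freqs):
        scale = wp / (2 * np.pi * f0)
        w = omega[pos] * scale
        # log-domain evaluation of (w/wp)^beta e^{wp^gamma - w^gamma}
        psi = np.zeros(n)
        psi[pos] = 2.0 * np.exp(
            beta * (np.log(w) - np.log(wp)) + wp**gam - w**gam
        )
        coef = np.fft.ifft(X * psi)
        tfr[j] = np.abs(coef) ** 2
    return freqs, tfr


def morse_density_profile(freqs, tfr, fs: float, params: MorseParams = MorseParams()):
    """Time-averaged TFR rescaled to a PSD-like density.

    Morse voices are constant-Q: their noise bandwidth grows linearly with
    center frequency, so the raw time-averaged magnitude-squared of a
    broadband process rises ~ f relative to its spectral density. Dividing
    each voice by its equivalent noise bandwidth (computed from the wavelet
    frequency response) makes the profile comparable to a Welch PSD.
    """
    freqs = np.asarray(freqs, dtype=float)
    beta, gam = params.beta, params.symmetry
    wp = params.peak_omega
    # equivalent noise bandwidth of the mother wavelet (peak value 2):
    # integral of |Psi|^2 over f, divided by peak^2
    w = np.linspace(1e-6, wp * 6, 20_000)
    psi2 = (
        2.0 * np.exp(beta * (np.log(w) - np.log(wp)) + wp**gam - w**gam)
    ) ** 2
    enbw_mother = np.trapezoid(psi2, w) / (2 * np.pi * 4.0)
    scales = wp / (2 * np.pi * freqs)
    enbw = enbw_mother / scales  # Hz, grows linearly with voice frequency
    profile = np.asarray(tfr).mean(axis=-1)
    return profile / enbw


def band_absolute_power(freqs, psd, band: BandDefinition) -> float:
    """Absolute power of a band: mean PSD over in-band bins (mV^2/Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    mask = band.mask(freqs)
    if not np.any(mask):
        df = np.median(np.diff(freqs)) if freqs.size > 1 else float("nan")
        raise ValueError(
            f"no frequency bins inside band {band.name} [{band.low}, "
            f"{band.high}] Hz at resolution {df} Hz"
        )
    return np.asarray(psd, dtype=float)[..., mask].mean(axis=-1)


def relative_power(ap_band: float, ap_total: float) -> float:
    """Relative power: band AP divided by total-band AP."""
    if np.any(np.asarray(ap_total) <= 0):
        raise ValueError("total absolute power must be > 0 (flat-zero spectrum)")
    return ap_band / ap_total


def baseline_and_change(power_per_segment):
    """Baseline (mean of five pre segments) and per-post-segment change.

    power_per_segment is the ten per-segment values ordered [-5,-4) ... [4,5).
    Returns (baseline, changes) where changes[j] = (post_j - baseline) /
    baseline for the five post segments [0,1) ... [4,5).
    """
    values = np.asarray(power_per_segment, dtype=float)
    if values.shape[-1] != N_SEGMENTS:
        raise ValueError(
            f"expected {N_SEGMENTS} segment values (5 pre + 5 post), got "
            f"{values.shape[-1]}"
        )
    pre = values[..., :N_PRE_SEGMENTS]
    post = values[..., N_PRE_SEGMENTS:]
    baseline = pre.mean(axis=-1)
    if np.any(baseline == 0):
        raise ValueError("baseline power is zero; normalised change undefined")
    changes = (post - baseline[..., None]) / baseline[..., None]
    return baseline, changes


def aggregate_trials(values) -> float:
    """Per-animal summary: arithmetic mean over trials."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one trial")
    return float(values.mean())


def aggregate_animals(values):
    """Group summary across animals: (mean, SEM).

    SEM = sample standard deviation / sqrt(N); NaN when N < 2.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one animal")
    mean = float(values.mean())
    if values.size < 2:
        return mean, float("nan")
    sem = float(values.std(ddof=1) / np.sqrt(values.size))
    return mean, sem


def band_power_table(
    session,
    bands: Sequence[BandDefinition] = (THETA, GAMMA),
    total_band: BandDefinition = TOTAL,
    welch: WelchParams = DEFAULT_WELCH,
    trial_average: bool = True,
) -> pd.DataFrame:
    """Tidy per-segment band-power table for one session.

    With ``trial_average=True`` (default) per-segment PSDs are averaged
    across trials *before* band-power extraction (trial-averaged spectrum);
    otherwise AP/RP are computed per trial and then averaged.

    Columns: band, segment_start_s, ap, rp, ap_baseline, rp_baseline,
    dap_over_ap, drp_over_rp (the change columns are NaN for pre segments).
    """
    grid = epoch_session(session)
    freqs, psd = welch_psd(grid.data, session.sampling_rate, welch)
    if trial_average:
        psd_seg = psd.mean(axis=0)  # (10, nfreq)
    else:
        psd_seg = psd  # (n_trials, 10, nfreq)

    rows = []
    ap_total = band_absolute_power(freqs, psd_seg, total_band)
    for band in bands:
        ap = band_absolute_power(freqs, psd_seg, band)
        rp = relative_power(ap, ap_total)
        if not trial_average:
            ap = ap.mean(axis=0)
            rp = rp.mean(axis=0)
        ap_base, dap = baseline_and_change(ap)
        rp_base, drp = baseline_and_change(rp)
        for s, start in enumerate(SEGMENT_STARTS_S):
            post = s - N_PRE_SEGMENTS
            rows.append(
                {
                    "band": band.name,
                    "segment_start_s": start,
                    "ap": ap[s],
                    "rp": rp[s],
                    "ap_baseline": ap_base,
                    "rp_baseline": rp_base,
                    "dap_over_ap": dap[post] if post >= 0 else np.nan,
                    "drp_over_rp": drp[post] if post >= 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
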