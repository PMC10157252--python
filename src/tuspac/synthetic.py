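"""Synthetic hippocampal LFP sessions with state-dependent rhythms and
stimulus-locked effects.

The generator emulates the statistical structure the analysis chain assumes
for CA1 recordings under three behavioral states (anesthesia, awake,
running):

* a 1/f^alpha background (fractional-noise spectrum over 1-100 Hz),
* a theta rhythm (8 Hz) and a gamma rhythm (40 Hz) whose Welch band powers
  match state-specific baselines (0.7 / 10.5 / 19.9 mV^2/Hz for theta),
* theta-phase amplitude modulation of the gamma rhythm (Tort-style
  construction) with state-specific modulation depth m,
* ultrasound-locked effects confined to [onset, onset + 2 s): per-1-s-bin
  constant power gains on theta and gamma (amplitudes scaled by sqrt(gain))
  and a multiplicative change of the coupling depth m, all modulated by
  stimulus pressure through signed per-state sensitivities.

Every generator is a pure function of (parameters, seed): one master seed
per session is split deterministically into independent background and
rhythm-phase streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .stimulus import StimulusProtocol, trial_onsets
from .spectral import DEFAULT_WELCH, THETA, GAMMA

__all__ = [
    "StateProfile",
    "LfpSession",
    "state_profile",
    "STATE_LABELS",
    "generate_background",
    "generate_coupled_rhythms",
    "apply_tus_effect",
    "generate_session",
]

STATE_LABELS = ("anesthesia", "awake", "running")

#: Duration of the stimulus-locked effect window after onset (s); gains are
#: piecewise constant over the 1-s analysis bins inside it.
EFFECT_DURATION_S = 2.0

#: Reference pressure (MPa) at which the per-state gains hold exactly; the
#: intensity sensitivities tilt the gains linearly around this point.
REFERENCE_PRESSURE_MPA = 0.45

#: Default background variance as a multiple of the state's theta baseline
#: power: large enough that the coupling estimator sits in its sensitive
#: (unsaturated) range for every state, small enough that in-band rhythm
#: dilution stays at the few-percent level.
NOISE_SCALE_FACTOR = 4.0

# Per-state defaults. Baseline band powers are the in-vivo pre-stimulus
# values per state; the power gains are calibrated so that the measured
# dAP/AP in the first two post-onset bins lands on the per-state group
# means (gain g yields dAP/AP = g - 1, up to a ~1-2% background dilution).
# The 1-2 s gamma gains decay like the theta effect (no printed value
# exists for that bin). PAC depth gains are > 1 where stimulation
# strengthens coupling (anesthesia, awake) and < 1 where it weakens it
# (running). Intensity sensitivities carry the dose-response sign pattern:
# under anesthesia theta relative power falls and gamma relative power and
# coupling rise with pressure; awake is the mirror image; running rises in
# theta with a mild coupling decrease.
_STATE_DEFAULTS = {
    "anesthesia": dict(
        theta_baseline_power=0.7,
        pac_depth_baseline=0.02,
        tus_theta_power_gain=(5.6, 3.1),
        tus_gamma_power_gain=(4.1, 2.4),
        tus_pac_depth_gain=1.45,
        intensity_sensitivity={"theta": -0.8, "gamma": 0.8, "pac": 0.8},
    ),
    "awake": dict(
        theta_baseline_power=10.5,
        pac_depth_baseline=0.15,
        tus_theta_power_gain=(3.7, 4.0),
        tus_gamma_power_gain=(2.7, 2.2),
        tus_pac_depth_gain=1.3,
        intensity_sensitivity={"theta": 0.8, "gamma": -0.8, "pac": -0.8},
    ),
    "running": dict(
        theta_baseline_power=19.9,
        pac_depth_baseline=0.35,
        tus_theta_power_gain=(1.07, 1.3),
        tus_gamma_power_gain=(1.3, 1.2),
        tus_pac_depth_gain=0.6,
        intensity_sensitivity={"theta": 0.8, "gamma": 0.0, "pac": 0.5},
    ),
}


@dataclass
class StateProfile:
    """Generative parameters for one behavioral state.

    theta_baseline_power and gamma_baseline_power are Welch absolute band
    powers (mean density, mV^2/Hz) of the rhythm-only signal; noise_scale is
    the background variance in mV^2 (default: numerically equal to the theta
    baseline times NOISE_SCALE_FACTOR, which keeps in-band rhythm dilution
    at the few-percent level while keeping the coupling estimator out of
    saturation). pac_depth_baseline is the modulation depth m in [0, 1).
    Gains are per-1-s-bin power multipliers over [onset, onset+2 s);
    intensity_sensitivity maps normalised pressure offsets to linear tilts
    of the excess gains (see :meth:`gains_at_pressure`).
    """

    state_label: str
    theta_baseline_power: float
    gamma_baseline_power: float
    pac_depth_baseline: float
    tus_theta_power_gain: tuple
    tus_gamma_power_gain: tuple
    tus_pac_depth_gain: float
    intensity_sensitivity: dict
    theta_center_frequency: float = 8.0
    gamma_center_frequency: float = 40.0
    noise_exponent: float = 1.0
    noise_scale: Optional[float] = None
    pac_phase_lag: float = 0.0
    theta_freq_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_baseline_power < 0 or self.gamma_baseline_power < 0:
            raise ValueError("baseline band powers must be >= 0")
        if not 0 <= self.pac_depth_baseline < 1:
            raise ValueError("pac_depth_baseline must be in [0, 1)")
        if not THETA.low <= self.theta_center_frequency <= THETA.high:
            raise ValueError("theta center frequency must lie inside 4-12 Hz")
        if not GAMMA.low <= self.gamma_center_frequency <= GAMMA.high:
            raise ValueError("gamma center frequency must lie inside 30-45 Hz")
        if self.noise_scale is None:
            self.noise_scale = float(NOISE_SCALE_FACTOR * self.theta_baseline_power)
        if self.pac_depth_baseline * abs(self.tus_pac_depth_gain) >= 1:
            raise ValueError(
                "m x pac depth gain must stay below 1 (gamma envelope "
                "would go negative)"
            )

    def gains_at_pressure(self, pressure_mpa: float) -> dict:
        """Effective gains at a stimulation pressure.

        Each excess gain (g - 1) is tilted linearly in the normalised
        pressure offset x = (p - 0.45) / 0.45 with the per-state signed
        sensitivity kappa: g(p) = 1 + (g_ref - 1) (1 + kappa x). Results
        are floored at 0 (power gains) and kept below 1/m (depth gain).
        """
        x = (pressure_mpa - REFERENCE_PRESSURE_MPA) / REFERENCE_PRESSURE_MPA
        k = self.intensity_sensitivity

        def tilt(g_ref, kappa):
            return max(0.0, 1.0 + (g_ref - 1.0) * (1.0 + kappa * x))

        theta = tuple(tilt(g, k.get("theta", 0.0)) for g in self.tus_theta_power_gain)
        gamma = tuple(tilt(g, k.get("gamma", 0.0)) for g in self.tus_gamma_power_gain)
        pac = tilt(self.tus_pac_depth_gain, k.get("pac", 0.0))
        if self.pac_depth_baseline * pac >= 1:
            pac = 0.999 / max(self.pac_depth_baseline, 1e-12)
        return {"theta": theta, "gamma": gamma, "pac": pac}


def state_profile(label: str, **overrides) -> StateProfile:
    """Build the default profile for a behavioral state, with overrides."""
    if label not in _STATE_DEFAULTS:
        raise ValueError(f"unknown state {label!r}; choose from {STATE_LABELS}")
    params = dict(_STATE_DEFAULTS[label])
    params.setdefault(
        "gamma_baseline_power", params["theta_baseline_power"] * 0.3
    )
    params.update(overrides)
    return StateProfile(state_label=label, **params)


@dataclass
class LfpSession:
    """A continuous single-channel LFP recording with stimulus metadata.

    samples are voltages in mV at ``sampling_rate`` Hz; stimulus_onsets are
    seconds from recording start; provenance echoes the generator
    parameters for reproducibility (empty for loaded real data).
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_onsets: np.ndarray
    state_label: str
    protocol: Optional[StimulusProtocol] = None
    seed: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.stimulus_onsets = np.asarray(self.stimulus_onsets, dtype=float)
        if np.any(np.isnan(self.samples)):
            raise ValueError("LFP samples contain NaN")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        for i, t in enumerate(self.stimulus_onsets):
            if t < 5.0 or t > dur - 5.0:
                raise ValueError(
                    f"stimulus onset {i} at {t} s lies closer than 5 s to a "
                    f"session edge (duration {dur:.3f} s)"
                )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def generate_background(
    duration: float, fs: float, exponent: float = 1.0, scale: float = 1.0,
    rng=None,
) -> np.ndarray:
    """Zero-mean 1/f^alpha background noise.

    White Gaussian noise is shaped in the frequency domain by
    f^(-alpha/2) (flat below 1 Hz to keep the variance finite), then
    rescaled so the realised variance equals ``scale`` (mV^2) exactly.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not 0 <= exponent <= 2:
        raise ValueError(f"noise exponent must be in [0, 2], got {exponent}")
    if scale < 0:
        raise ValueError("noise scale (variance) must be >= 0")
    rng = np.random.default_rng(rng)
    n = int(round(duration * fs))
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    weights = np.maximum(f, 1.0) ** (-exponent / 2.0)
    weights[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * weights, n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x *= np.sqrt(scale) / sd
    return x


def _rhythm_amplitudes(profile: StateProfile, welch=DEFAULT_WELCH, fs=1000.0):
    """Tone amplitudes that put the Welch band powers on the profile baselines.

    A tone of amplitude A at a Welch bin center carries integrated power
    A^2/2, so its mean in-band density is A^2 / (2 df n_bins). The gamma
    amplitude additionally divides out the modulation power factor
    (1 + m^2/2).
    """
    df = welch.resolution(fs)
    grid = np.arange(0.0, fs / 2 + df / 2, df)
    n_theta = int(THETA.mask(grid).sum())
    n_gamma = int(GAMMA.mask(grid).sum())
    m = profile.pac_depth_baseline
    a_theta = np.sqrt(2.0 * profile.theta_baseline_power * df * n_theta)
    a_gamma = np.sqrt(
        2.0 * profile.gamma_baseline_power * df * n_gamma / (1.0 + m**2 / 2.0)
    )
    return a_theta, a_gamma


def generate_coupled_rhythms(
    duration: float, fs: float, profile: StateProfile, rng=None,
    return_components: bool = False,
):
    """Theta rhythm plus theta-phase-modulated gamma rhythm.

    x(t) = A_th cos(phi_th(t))
         + A_ga [1 + m cos(phi_th(t) - phi0)] cos(2 pi f_ga t + psi)

    with phi_th(t) = 2 pi f_th t + phase offset (plus optional
    Ornstein-Uhlenbeck frequency jitter, off by default so the construction
    stays analytic). Amplitudes are set so the Welch band powers of the
    rhythm-only signal match the profile baselines in expectation.

    With ``return_components=True`` also returns the decomposition needed
    to re-scale the rhythms inside stimulation windows: theta component,
    gamma carrier, theta phase, and the amplitude/depth parameters.
    """
    if profile.pac_depth_baseline >= 1:
        raise ValueError("modulation depth m must be < 1 (negative envelope)")
    rng = np.random.default_rng(rng)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    a_theta, a_gamma = _rhythm_amplitudes(profile, fs=fs)
    phase0 = rng.uniform(0, 2 * np.pi)
    psi = rng.uniform(0, 2 * np.pi)
    phi = 2 * np.pi * profile.theta_center_frequency * t + phase0
    if profile.theta_freq_jitter > 0:
        # OU frequency drift integrated into the phase
        tau, sd = 1.0, profile.theta_freq_jitter
        dt = 1.0 / fs
        drift = np.empty(n)
        drift[0] = 0.0
        eps = rng.standard_normal(n - 1)
        for i in range(1, n):
            drift[i] = drift[i - 1] * (1 - dt / tau) + sd * np.sqrt(
                2 * dt / tau
            ) * eps[i - 1]
        phi = phi + 2 * np.pi * np.cumsum(drift) / fs
    theta = a_theta * np.cos(phi)
    carrier = np.cos(2 * np.pi * profile.gamma_center_frequency * t + psi)
    m = profile.pac_depth_baseline
    gamma = a_gamma * (1.0 + m * np.cos(phi - profile.pac_phase_lag)) * carrier
    signal = theta + gamma
    if not return_components:
        return signal
    components = {
        "theta": theta,
        "carrier": carrier,
        "theta_phase": phi,
        "a_gamma": a_gamma,
        "m": m,
        "phase_lag": profile.pac_phase_lag,
    }
    return signal, components


def apply_tus_effect(
    clean,
    onsets,
    profile: StateProfile,
    protocol: StimulusProtocol,
    fs: float = 1000.0,
    components: Optional[dict] = None,
    pressure_mpa: Optional[float] = None,
) -> np.ndarray:
    """Impose stimulus-locked power and coupling changes on a rhythm signal.

    Inside each [onset, onset + 2 s) window the theta and gamma amplitudes
    are scaled by sqrt(power gain) (constant per 1-s bin) and the coupling
    depth m by the state's depth gain; the signal is untouched elsewhere.
    Re-scaling m requires the generative decomposition from
    :func:`generate_coupled_rhythms` (``components``); with all gains equal
    to 1 the input is returned unchanged for any signal.
    """
    clean = np.asarray(clean, dtype=float)
    onsets = np.sort(np.asarray(onsets, dtype=float))
    if onsets.size > 1 and np.any(np.diff(onsets) < EFFECT_DURATION_S):
        raise ValueError("stimulus effect windows overlap")
    pressure = (
        pressure_mpa if pressure_mpa is not None else protocol.peak_pressure
    )
    gains = profile.gains_at_pressure(pressure)
    n_bins = int(EFFECT_DURATION_S)
    trivial = (
        all(g == 1.0 for g in gains["theta"][:n_bins])
        and all(g == 1.0 for g in gains["gamma"][:n_bins])
        and gains["pac"] == 1.0
    )
    if trivial:
        return clean.copy()
    if components is None:
        raise ValueError(
            "re-scaling rhythm amplitudes and coupling depth requires the "
            "component decomposition from generate_coupled_rhythms(..., "
            "return_components=True)"
        )
    out = clean.copy()
    theta = components["theta"]
    carrier = components["carrier"]
    phi = components["theta_phase"]
    a_gamma = components["a_gamma"]
    m = components["m"]
    lag = components["phase_lag"]
    bin_len = int(round(fs))
    m_eff = m * gains["pac"]
    if m_eff >= 1:
        raise ValueError("scaled modulation depth must stay below 1")
    for onset in onsets:
        start = int(round(onset * fs))
        for b in range(n_bins):
            lo, hi = start + b * bin_len, start + (b + 1) * bin_len
            if lo < 0 or hi > clean.size:
                raise ValueError(
                    f"effect window for onset {onset} s exceeds the signal"
                )
            g_th = gains["theta"][b]
            g_ga = gains["gamma"][b]
            sl = slice(lo, hi)
            out[sl] = np.sqrt(g_th) * theta[sl] + np.sqrt(g_ga) * a_gamma * (
                1.0 + m_eff * np.cos(phi[sl] - lag)
            ) * carrier[sl]
    return out


def generate_session(
    profile: StateProfile,
    protocol: Optional[StimulusProtocol] = None,
    duration: Optional[float] = None,
    seed: int = 0,
    start: float = 10.0,
    fs: float = 1000.0,
) -> LfpSession:
    """Compose a full synthetic session: rhythms + stimulus effects + noise.

    Deterministic given (parameters, seed): the master seed is split into
    independent background and rhythm-phase streams, so identical seeds
    yield bit-identical sessions.
    """
    protocol = protocol if protocol is not None else StimulusProtocol()
    onsets = trial_onsets(protocol, start)
    minimum = float(onsets[-1] + 5.0)
    if duration is None:
        duration = minimum + 1.0
    if duration < minimum:
        raise ValueError(
            f"duration {duration} s too short for {protocol.n_trials} trials; "
            f"need at least {minimum} s"
        )
    ss = np.random.SeedSequence(seed)
    bg_seed, rhythm_seed = ss.spawn(2)
    clean, components = generate_coupled_rhythms(
        duration, fs, profile, rng=np.random.default_rng(rhythm_seed),
        return_components=True,
    )
    with_effect = apply_tus_effect(
        clean, onsets, profile, protocol, fs=fs, components=components
    )
    background = generate_background(
        duration,
        fs,
        exponent=profile.noise_exponent,
        scale=profile.noise_scale,
        rng=np.random.default_rng(bg_seed),
    )
    samples = with_effect + background
    provenance = asdict(profile)
    provenance["protocol"] = protocol.to_dict()
    provenance["seed"] = seed
    provenance["start_s"] = start
    provenance["duration_s"] = duration
    return LfpSession(
        samples=samples,
        sampling_rate=fs,
        stimulus_onsets=onsets,
        state_label=profile.state_label,
        protocol=protocol,
        seed=seed,
        provenance=provenance,
    )
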