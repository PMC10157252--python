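"""Ultrasound stimulation protocol and plane-wave acoustic dosimetry.

The stimulation used here is a pulsed low-intensity transcranial ultrasound
burst: a 2.25 MHz carrier gated at a 1 kHz pulse-repetition frequency with a
50% duty cycle for 400 ms per trial, repeated over a fixed trial schedule.
Because analysis runs on 1 kHz local-field-potential recordings, the MHz
carrier is never synthesized at sample level; the stimulus is represented by
its pulse envelope, trial timing, and acoustic dose.

Dose is expressed as the spatial-peak pulse-average intensity Isppa of a
plane wave, I = p^2 / (2 Z), with p the peak pressure and Z the
characteristic acoustic impedance of the medium (1.5e6 Pa·s/m for
water / soft tissue).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcousticMedium",
    "StimulusProtocol",
    "pressure_to_isppa",
    "isppa_to_pressure",
    "build_pulse_envelope",
    "trial_onsets",
]

#: Half-width of the peristimulus analysis window (s): ten 1-s segments
#: spanning [-5, 5) around each stimulus onset.
EPOCH_HALF_WIDTH_S = 5.0

#: Minimum inter-trial interval (s) so consecutive [-5, 5) windows are disjoint.
MIN_INTER_TRIAL_INTERVAL_S = 2 * EPOCH_HALF_WIDTH_S


@dataclass(frozen=True)
class AcousticMedium:
    """Propagation medium for plane-wave dosimetry.

    Parameters
    ----------
    characteristic_impedance : float
        Acoustic impedance Z in Pa·s/m. Default 1.5e6 (water / soft tissue).
    """

    characteristic_impedance: float = 1.5e6

    def __post_init__(self) -> None:
        if not self.characteristic_impedance > 0:
            raise ValueError(
                f"characteristic_impedance must be > 0, got "
                f"{self.characteristic_impedance}"
            )


WATER = AcousticMedium()


@dataclass
class StimulusProtocol:
    """Timing and dose parameters of one pulsed-ultrasound session.

    Parameters
    ----------
    fundamental_frequency : float
        Carrier frequency FF in Hz (metadata only; never sampled).
    pulse_repetition_frequency : float
        PRF in Hz; pulses per second within a burst.
    stimulation_duration : float
        Burst length SD per trial, in seconds.
    duty_cycle : float
        Fraction of each pulse period with the carrier on, in (0, 1].
    peak_pressure : float
        Peak acoustic pressure in MPa.
    n_trials : int
        Number of stimulation trials per session.
    inter_trial_interval : float
        Onset-to-onset spacing in seconds; must be >= 10 s so the
        [-5, 5) s analysis windows of consecutive trials cannot overlap.
    """

    fundamental_frequency: float = 2.25e6
    pulse_repetition_frequency: float = 1000.0
    stimulation_duration: float = 0.400
    duty_cycle: float = 0.5
    peak_pressure: float = 0.45
    n_trials: int = 16
    inter_trial_interval: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "fundamental_frequency",
            "pulse_repetition_frequency",
            "stimulation_duration",
            "inter_trial_interval",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")
        if self.peak_pressure < 0:
            raise ValueError("peak_pressure must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.inter_trial_interval < MIN_INTER_TRIAL_INTERVAL_S:
            raise ValueError(
                f"inter_trial_interval must be >= {MIN_INTER_TRIAL_INTERVAL_S} s "
                f"(the [-5, 5) s epoch windows of consecutive trials would "
                f"overlap), got {self.inter_trial_interval}"
            )

    @property
    def pulse_on_time(self) -> float:
        """On-time of each pulse in seconds: duty_cycle / PRF."""
        return self.duty_cycle / self.pulse_repetition_frequency

    @property
    def n_pulses(self) -> int:
        """Pulses per trial: round(SD * PRF)."""
        return int(round(self.stimulation_duration * self.pulse_repetition_frequency))

    # serialization uses short config keys (ff_hz, prf_hz, ...)
    _KEYMAP = {
        "fundamental_frequency": "ff_hz",
        "pulse_repetition_frequency": "prf_hz",
        "stimulation_duration": "duration_s",
        "duty_cycle": "duty_cycle",
        "peak_pressure": "pressure_mpa",
        "n_trials": "n_trials",
        "inter_trial_interval": "iti_s",
    }

    def to_dict(self) -> dict:
        return {short: getattr(self, attr) for attr, short in self._KEYMAP.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        inverse = {short: attr for attr, short in cls._KEYMAP.items()}
        kwargs = {}
        for key, value in d.items():
            if key in inverse:
                kwargs[inverse[key]] = value
            elif key in cls._KEYMAP:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown protocol key {key!r}")
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        return cls.from_dict(json.loads(text))


def pressure_to_isppa(pressure_mpa, medium: AcousticMedium = WATER):
    """Convert peak pressure (MPa) to plane-wave Isppa (W/cm^2).

    I = p^2 / (2 Z), with p in Pa and Z the characteristic impedance;
    the result is converted from W/m^2 to W/cm^2.
    """
    p = np.asarray(pressure_mpa, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be >= 0")
    pa = p * 1e6
    intensity_w_m2 = pa**2 / (2.0 * medium.characteristic_impedance)
    out = intensity_w_m2 / 1e4
    return float(out) if np.isscalar(pressure_mpa) else out


def isppa_to_pressure(intensity_w_cm2, medium: AcousticMedium = WATER):
    """Inverse of :func:`pressure_to_isppa`: Isppa (W/cm^2) to pressure (MPa)."""
    i = np.asarray(intensity_w_cm2, dtype=float)
    if np.any(i < 0):
        raise ValueError("intensity must be >= 0")
    pa = np.sqrt(2.0 * medium.characteristic_impedance * i * 1e4)
    out = pa / 1e6
    return float(out) if np.isscalar(intensity_w_cm2) else out


def build_pulse_envelope(protocol: StimulusProtocol, sampling_rate: float) -> np.ndarray:
    """Binary on/off envelope over one trial's stimulation window.

    Sample i (time t = i / fs) is on when the phase within the current pulse
    period is below the duty cycle. Requires fs >= 2 * PRF so each pulse
    period spans at least two samples (Nyquist for the pulse train).
    """
    prf = protocol.pulse_repetition_frequency
    if sampling_rate < 2 * prf:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz is below the Nyquist constraint "
            f"2 * PRF = {2 * prf} Hz for a {prf} Hz pulse train"
        )
    n = int(round(protocol.stimulation_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    phase = (t * prf) % 1.0
    return (phase < protocol.duty_cycle).astype(np.uint8)


def trial_onsets(protocol: StimulusProtocol, start: float) -> np.ndarray:
    """Evenly spaced stimulus onset times (s) for all trials in a session."""
    if protocol.inter_trial_interval < MIN_INTER_TRIAL_INTERVAL_S:
        raise ValueError(
            f"inter_trial_interval must be >= {MIN_INTER_TRIAL_INTERVAL_S} s "
            f"so that peristimulus windows never overlap"
        )
    return start + np.arange(protocol.n_trials) * protocol.inter_trial_interval
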