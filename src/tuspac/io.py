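"""Reading and writing LFP sessions, event files, and configs.

Supported on-disk formats:

* delimited text (CSV/TSV) with columns ``time_s, voltage_mv`` (or a single
  ``voltage_mv`` column plus an explicit sampling rate),
* 16-bit EDF (European Data Format) with physical dimension mV, through a
  minimal single-purpose reader/writer,
* events as TSV with columns ``trial_index, onset_s``,
* configs as YAML or JSON.

Loading never mutates sample values: no implicit filtering, detrending, or
unit rescaling beyond the format's own physical calibration. Time is in
seconds with t = 0 at file start; intervals are half-open [a, b).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .synthetic import LfpSession

__all__ = [
    "read_lfp",
    "write_lfp",
    "read_events",
    "write_events",
    "extract_trigger_onsets",
    "load_config",
    "SessionBundle",
    "configure_logging",
]

logger = logging.getLogger("tuspac")

#: Tolerance (s) for uniform spacing of an explicit time column.
TIME_UNIFORMITY_TOL_S = 1e-6


def configure_logging(verbosity: int = 0) -> None:
    """Route package logging to stderr; verbosity -1/0/1 = quiet/info/debug."""
    level = {-1: logging.WARNING, 0: logging.INFO, 1: logging.DEBUG}.get(
        verbosity, logging.DEBUG
    )
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "tsv", "edf"}:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_lfp(
    path,
    format: Optional[str] = None,
    sampling_rate: Optional[float] = None,
    channel: Optional[str] = None,
    state_label: str = "unknown",
) -> LfpSession:
    """Load a single-channel LFP recording (without events).

    CSV/TSV files need either a ``time_s`` column (validated for uniform
    spacing to 1e-6 s) or an explicit ``sampling_rate``. Multichannel EDF
    files need a ``channel`` label selector.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if "voltage_mv" not in df.columns:
            raise ValueError(
                f"{path.name}: expected a 'voltage_mv' column, got "
                f"{list(df.columns)}"
            )
        samples = df["voltage_mv"].to_numpy(dtype=float)
        if "time_s" in df.columns:
            t = df["time_s"].to_numpy(dtype=float)
            dt = np.diff(t)
            if dt.size == 0:
                raise ValueError(f"{path.name}: need at least two samples")
            step = np.median(dt)
            if step <= 0 or np.any(np.abs(dt - step) > TIME_UNIFORMITY_TOL_S):
                raise ValueError(
                    f"{path.name}: time column is not uniformly spaced "
                    f"(tolerance {TIME_UNIFORMITY_TOL_S} s)"
                )
            fs = 1.0 / step
        elif sampling_rate is not None:
            fs = float(sampling_rate)
        else:
            raise ValueError(
                f"{path.name}: no time_s column; pass sampling_rate explicitly"
            )
    elif fmt == "edf":
        samples, fs = _read_edf(path, channel=channel)
    else:
        raise ValueError(f"unsupported format {fmt!r}; choose csv, tsv, or edf")
    logger.info("loaded %s: %d samples at %g Hz", path.name, samples.size, fs)
    return LfpSession(
        samples=samples,
        sampling_rate=fs,
        stimulus_onsets=np.empty(0),
        state_label=state_label,
    )


def write_lfp(path, session: LfpSession, format: Optional[str] = None) -> None:
    """Write a session's samples to CSV/TSV (time_s, voltage_mv) or EDF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        t = np.arange(session.samples.size) / session.sampling_rate
        pd.DataFrame({"time_s": t, "voltage_mv": session.samples}).to_csv(
            path, sep=sep, index=False
        )
    elif fmt == "edf":
        _write_edf(path, session.samples, session.sampling_rate)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# --------------------------------------------------------------------------
# Minimal EDF (16-bit) support. The format is a 256-byte ASCII header, one
# 256-byte ASCII header per signal, then data records of little-endian
# 16-bit integers mapped linearly from the digital to the physical range.
# Records are 1 s long; the final record is zero-padded to a whole second.
# --------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, samples: np.ndarray, fs: float, labels=None) -> None:
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    ns = x.shape[0]
    if labels is None:
        labels = ["LFP"] if ns == 1 else [f"LFP{i}" for i in range(ns)]
    n_records = int(np.ceil(x.shape[1] / fs_i))
    padded = np.zeros((ns, n_records * fs_i))
    padded[:, : x.shape[1]] = x
    phys_max = np.abs(padded).max(axis=1)
    phys_max[phys_max == 0] = 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(
        np.round((padded + phys_max[:, None]) * scale[:, None]) + dig_min,
        dig_min,
        dig_max,
    ).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),  # patient id
            _ascii("X", 80),  # recording id
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 + 256 * ns, 8),  # header bytes
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),  # record duration (s)
            _ascii(ns, 4),  # number of signals
        ]
    )

    def per_signal(width, values):
        return b"".join(_ascii(v, width) for v in values)

    sig_header = b"".join(
        [
            per_signal(16, labels),
            per_signal(80, ["synthetic LFP"] * ns),
            per_signal(8, ["mV"] * ns),
            per_signal(8, [f"{-m:.6g}" for m in phys_max]),
            per_signal(8, [f"{m:.6g}" for m in phys_max]),
            per_signal(8, [dig_min] * ns),
            per_signal(8, [dig_max] * ns),
            per_signal(80, [""] * ns),
            per_signal(8, [fs_i] * ns),
            per_signal(32, [""] * ns),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for c in range(ns):
                fh.write(digital[c, r * fs_i : (r + 1) * fs_i].tobytes())


def _read_edf(path: Path, channel: Optional[str] = None):
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path.name}: truncated EDF header")
        header_bytes = int(head[184:192].decode("ascii").strip())
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())

        def fields(width):
            return [
                fh.read(width).decode("ascii").strip() for _ in range(ns)
            ]

        labels = fields(16)
        fields(80)  # transducer
        dims = fields(8)
        phys_min = [float(v) for v in fields(8)]
        phys_max = [float(v) for v in fields(8)]
        dig_min = [int(v) for v in fields(8)]
        dig_max = [int(v) for v in fields(8)]
        fields(80)  # prefilter
        spr = [int(v) for v in fields(8)]
        fields(32)  # reserved
        fh.seek(header_bytes)
        data = fh.read()

    if ns > 1 and channel is None:
        raise ValueError(
            f"{path.name} has {ns} channels; pass channel= to select one of "
            f"{labels}"
        )
    idx = 0 if channel is None else labels.index(channel)
    if dims[idx].lower() not in {"mv", ""}:
        warnings.warn(
            f"{path.name}: unknown physical dimension {dims[idx]!r}; "
            f"assuming mV",
            stacklevel=2,
        )
    record_len = sum(spr)
    raw = np.frombuffer(data, dtype="<i2")
    raw = raw[: n_records * record_len].reshape(n_records, record_len)
    offset = sum(spr[:idx])
    digital = raw[:, offset : offset + spr[idx]].reshape(-1).astype(float)
    gain = (phys_max[idx] - phys_min[idx]) / (dig_max[idx] - dig_min[idx])
    physical = (digital - dig_min[idx]) * gain + phys_min[idx]
    fs = spr[idx] / record_dur
    return physical, fs


def read_events(path, session_duration: Optional[float] = None) -> np.ndarray:
    """Load stimulus onset times (s) from a TSV with an ``onset_s`` column.

    Onsets must be strictly increasing; with ``session_duration`` given,
    each onset must keep a 5 s margin to both recording edges (the epoching
    precondition).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "onset_s" not in df.columns:
        raise ValueError(f"{path.name}: expected an 'onset_s' column")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if onsets.size == 0:
        raise ValueError(f"{path.name}: no trials in event file")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(
            f"{path.name}: onsets must be strictly increasing (no duplicates)"
        )
    if session_duration is not None:
        for i, t in enumerate(onsets):
            if t < 5.0 or t > session_duration - 5.0:
                raise ValueError(
                    f"trial {i} onset at {t} s lies closer than 5 s to a "
                    f"recording edge ({session_duration:.3f} s long)"
                )
    logger.info("loaded %d stimulus onsets from %s", onsets.size, path.name)
    return onsets


def write_events(path, onsets: Sequence[float]) -> None:
    """Write onset times as a two-column TSV (trial_index, onset_s)."""
    onsets = np.asarray(onsets, dtype=float)
    pd.DataFrame(
        {"trial_index": np.arange(onsets.size), "onset_s": onsets}
    ).to_csv(path, sep="\t", index=False)


def extract_trigger_onsets(
    trigger,
    fs: float,
    threshold: Optional[float] = None,
    refractory: float = 0.1,
) -> np.ndarray:
    """Onset times from a raw trigger channel.

    Rising edges above the threshold (default: half the channel maximum).
    An edge starts a new trial only if the channel stayed below threshold
    for the full refractory period (default 100 ms) beforehand, so the
    individual pulses of a burst's pulse train do not re-trigger.
    """
    x = np.asarray(trigger, dtype=float)
    if threshold is None:
        threshold = x.max() / 2.0
    above = x >= threshold
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    refractory_samples = int(round(refractory * fs))
    above_idx = np.flatnonzero(above)
    keep = []
    for e in edges:
        prior = above_idx[above_idx < e]
        if prior.size == 0 or e - prior[-1] > refractory_samples:
            keep.append(e)
    return np.asarray(keep, dtype=float) / fs


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


@dataclass
class SessionBundle:
    """Paths of one recording's files, resolvable into an LfpSession."""

    lfp_path: str
    events_path: str
    state_label: str
    config_path: Optional[str] = None
    format: Optional[str] = None
    sampling_rate: Optional[float] = None
    channel: Optional[str] = None

    def load(self, expected_rate: Optional[float] = None) -> LfpSession:
        """Read LFP + events; resample if the file rate differs from the
        expected rate (polyphase resampling, logged)."""
        session = read_lfp(
            self.lfp_path,
            format=self.format,
            sampling_rate=self.sampling_rate,
            channel=self.channel,
            state_label=self.state_label,
        )
        samples, fs = session.samples, session.sampling_rate
        if expected_rate is not None and abs(fs - expected_rate) > 1e-9:
            from scipy.signal import resample_poly
            from fractions import Fraction

            frac = Fraction(expected_rate / fs).limit_denominator(1000)
            logger.warning(
                "resampling %s from %g to %g Hz", self.lfp_path, fs,
                expected_rate,
            )
            samples = resample_poly(samples, frac.numerator, frac.denominator)
            fs = expected_rate
        onsets = read_events(
            self.events_path, session_duration=samples.size / fs
        )
        return LfpSession(
            samples=samples,
            sampling_rate=fs,
            stimulus_onsets=onsets,
            state_label=self.state_label,
        )
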