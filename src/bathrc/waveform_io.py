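"""Waveform logging: file I/O, co-registration and synthetic recordings.

Flow/pressure logs are plain CSV (comma separator, ``.`` decimal, one header
row) with a ``time_s`` column and any of the recognised channel columns
``flow_Lps``, ``pressure_cmH2O``, ``volume_L``; unrecognised columns are
carried through untouched.  Two loggers recording the same experiment start
at slightly different times, so records are co-registered by maximising the
cross-correlation of a shared channel.

The synthetic generator samples the model's cyclic steady state the way the
bench loggers would have seen it -- 50 Hz, additive Gaussian instrument
noise, and an inter-logger start offset -- so the characterisation procedures
are testable without any recorded dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .exceptions import AlignmentError, FormatError, InvalidParameterError
from .rc_core import (
    CircuitParams,
    LungParams,
    VentSettings,
    phase_timing,
    steady_state_waveforms,
)

__all__ = [
    "WaveformRecord",
    "read_waveform",
    "write_waveform",
    "coregister",
    "generate_synthetic",
    "synthetic_blocked_line",
]

# channel name <-> file column
_COLUMN_OF = {"flow": "flow_Lps", "pressure": "pressure_cmH2O", "volume": "volume_L"}
_CHANNEL_OF = {v: k for k, v in _COLUMN_OF.items()}
_TIME_COL = "time_s"


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled multi-channel recording.

    ``channels`` maps channel names (``flow``, ``pressure``, ``volume`` or a
    raw column name for unrecognised channels) to equal-length float arrays.
    """

    sample_rate: float
    channels: dict[str, np.ndarray]
    source: str = ""
    t0: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidParameterError(
                f"sample_rate must be > 0, got {self.sample_rate}"
            )
        if not self.channels:
            raise InvalidParameterError("record must have at least one channel")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise InvalidParameterError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        data = {_TIME_COL: self.time}
        for name, values in self.channels.items():
            data[_COLUMN_OF.get(name, name)] = values
        return pd.DataFrame(data)


def write_waveform(record: WaveformRecord, path) -> None:
    """Write a record as CSV with the canonical column names."""
    record.to_frame().to_csv(path, index=False)


def read_waveform(path, source: str | None = None) -> WaveformRecord:
    """Read a CSV waveform log.

    Requires a ``time_s`` column with uniform sampling (relative jitter above
    1% of the median step is rejected); every other column becomes a channel.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if _TIME_COL not in frame.columns:
        raise FormatError(f"{path}: missing required column '{_TIME_COL}'")
    if len(frame) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t = frame[_TIME_COL].to_numpy(dtype=float)
    steps = np.diff(t)
    dt = np.median(steps)
    if dt <= 0:
        raise FormatError(f"{path}: time column is not increasing")
    if np.max(np.abs(steps - dt)) > 0.01 * dt:
        raise FormatError(
            f"{path}: non-uniform sampling (gap or jitter beyond 1% of the "
            f"{dt:g} s step)"
        )
    channels = {
        _CHANNEL_OF.get(col, col): frame[col].to_numpy(dtype=float)
        for col in frame.columns
        if col != _TIME_COL
    }
    if not channels:
        raise FormatError(f"{path}: no data channels besides '{_TIME_COL}'")
    return WaveformRecord(
        sample_rate=1.0 / dt,
        channels=channels,
        source=source if source is not None else str(path),
        t0=float(t[0]),
    )


# ---------------------------------------------------------------------------
# Co-registration
# ---------------------------------------------------------------------------


def coregister(
    rec_a: WaveformRecord,
    rec_b: WaveformRecord,
    channel: str,
    max_lag: float = 10.0,
) -> tuple[WaveformRecord, WaveformRecord, float]:
    """Align two recordings of the same experiment on a shared channel.

    The integer-sample lag maximising the cross-correlation of the named
    channel (search bounded to ``+-max_lag`` seconds) is applied and both
    records are trimmed to the overlap.  A positive lag means ``rec_b``
    started later than ``rec_a``.

    Returns ``(aligned_a, aligned_b, lag_seconds)``.
    """
    for rec, label in ((rec_a, "rec_a"), (rec_b, "rec_b")):
        if channel not in rec.channels:
            raise AlignmentError(f"{label} has no channel '{channel}'")
        if rec.duration < 5.0:
            raise AlignmentError(
                f"{label} is only {rec.duration:.2f} s long; need >= 5 s overlap"
            )
    if abs(rec_a.sample_rate - rec_b.sample_rate) > 1e-9 * rec_a.sample_rate:
        raise AlignmentError("records have different sample rates")
    fs = rec_a.sample_rate
    a = rec_a.channels[channel].astype(float)
    b = rec_b.channels[channel].astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AlignmentError(
            f"channel '{channel}' has zero variance; alignment impossible"
        )
    corr = correlate(b - b.mean(), a - a.mean(), mode="full")
    # displacement d: corr index k corresponds to d = k - (len(a) - 1),
    # and corr[k] = sum_n b[n] a[n - d]; d > 0 means b lags a.
    disp = np.arange(-(len(a) - 1), len(b))
    window = np.abs(disp) <= int(round(max_lag * fs))
    if not window.any():
        raise AlignmentError(f"max_lag {max_lag} s shorter than one sample")
    k = np.flatnonzero(window)[np.argmax(corr[window])]
    d = int(disp[k])

    # pair (a[i], b[i + d]) over the valid range
    if d >= 0:
        n = min(len(a), len(b) - d)
        sl_a, sl_b = slice(0, n), slice(d, d + n)
    else:
        n = min(len(a) + d, len(b))
        sl_a, sl_b = slice(-d, -d + n), slice(0, n)
    if n < 1:
        raise AlignmentError("no overlap after alignment")
    out_a = replace(
        rec_a, channels={k_: v[sl_a] for k_, v in rec_a.channels.items()}
    )
    out_b = replace(
        rec_b, channels={k_: v[sl_b] for k_, v in rec_b.channels.items()}, t0=rec_a.t0
    )
    return out_a, out_b, d / fs


# ---------------------------------------------------------------------------
# Synthetic recordings
# ---------------------------------------------------------------------------

#: Realistic instrument noise for a bench flow analyser: ~0.1 cmH2O on
#: pressure, ~0.01 L/s on flow; volume is integrated in the instrument and
#: left noise-free by default.
DEFAULT_NOISE_SD = {"pressure": 0.1, "flow": 0.01}


def generate_synthetic(
    lung: LungParams,
    circuit: CircuitParams,
    settings: VentSettings,
    noise_sd: dict[str, float] | None = None,
    logger_offset: float = 0.0,
    n_breaths: int = 10,
    sample_rate: float = 50.0,
    seed: int | None = None,
) -> tuple[WaveformRecord, WaveformRecord]:
    """Emulate a pair of logger recordings of the cyclic steady state.

    Both loggers see the same underlying waveforms (patient flow, airway
    pressure at the tubing node, lung volume); logger B starts
    ``logger_offset`` seconds after logger A, so its trace appears delayed.
    Independent Gaussian noise (standard deviations per channel in
    ``noise_sd``; pass ``{}`` for none, ``None`` for the defaults) is added to
    each logger.  Deterministic for a fixed seed.
    """
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be > 0")
    if n_breaths < 1:
        raise InvalidParameterError("n_breaths must be >= 1")
    sd = dict(DEFAULT_NOISE_SD) if noise_sd is None else dict(noise_sd)
    period = phase_timing(settings).period
    n = int(round(n_breaths * period * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)

    records = []
    for label, offset in (("logger_a", 0.0), ("logger_b", logger_offset)):
        w = steady_state_waveforms(lung, circuit, settings, t - offset)
        channels = {
            "flow": w["q_patient"].copy(),
            "pressure": w["p_tube"].copy(),
            "volume": w["volume"].copy(),
        }
        for name in channels:
            if sd.get(name, 0.0) > 0:
                channels[name] = channels[name] + rng.normal(
                    0.0, sd[name], size=n
                )
        records.append(
            WaveformRecord(sample_rate=sample_rate, channels=channels, source=label)
        )
    return records[0], records[1]


def synthetic_blocked_line(
    circuit: CircuitParams,
    settings: VentSettings,
    noise_sd: dict[str, float] | None = None,
    n_breaths: int = 10,
    sample_rate: float = 50.0,
    seed: int | None = None,
) -> WaveformRecord:
    """Recording of a blocked tubing run (no patient attached).

    With the line blocked, all delivered gas is stored in the tubing
    compliance: the node pressure relaxes toward the drive with time constant
    ``R_series * Cv`` in each phase and the line flow is
    ``(p_drive - p) / R_series``.  Used to estimate ``Cv``.
    """
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be > 0")
    timing = phase_timing(settings)
    p_i = settings.peep + settings.pinsp
    p_e = settings.peep
    rs_i = circuit.series_resistance("insp")
    rs_e = circuit.series_resistance("exp")
    n = int(round(n_breaths * timing.period * sample_rate))
    t = np.arange(n) / sample_rate
    tc = np.mod(t, timing.period)
    insp = tc < timing.t_insp

    if circuit.c_v == 0:
        # no storage: node pressure follows the drive, no flow
        pressure = np.where(insp, p_i, p_e).astype(float)
        flow = np.zeros(n)
    else:
        tau_i = rs_i * circuit.c_v
        tau_e = rs_e * circuit.c_v
        e_i = np.exp(-timing.t_insp / tau_i)
        e_e = np.exp(-timing.t_exp / tau_e)
        # cyclic fixed point of the scalar two-phase map
        p0 = (p_e * (1 - e_e) + e_e * p_i * (1 - e_i)) / (1 - e_i * e_e)
        p_sw = p_i + (p0 - p_i) * e_i
        pressure = np.where(
            insp,
            p_i + (p0 - p_i) * np.exp(-tc / tau_i),
            p_e + (p_sw - p_e) * np.exp(-(tc - timing.t_insp) / tau_e),
        )
        flow = np.where(insp, (p_i - pressure) / rs_i, (p_e - pressure) / rs_e)

    sd = dict(DEFAULT_NOISE_SD) if noise_sd is None else dict(noise_sd)
    rng = np.random.default_rng(seed)
    channels = {"flow": flow, "pressure": pressure}
    for name in channels:
        if sd.get(name, 0.0) > 0:
            channels[name] = channels[name] + rng.normal(0.0, sd[name], size=n)
    return WaveformRecord(
        sample_rate=sample_rate, channels=channels, source="blocked_line"
    )
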