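"""Reading and preprocessing of raw skin-conductance recordings.

Raw traces are band-pass filtered with a causal (single-pass, forward
only) Butterworth filter between 0.0159 Hz and 5 Hz — the high-pass
removes the slowly drifting conductance level, the low-pass serves as an
anti-alias stage — and then decimated to the 10 Hz analysis grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal import ScSignal

DEFAULT_LOW_HZ = 0.0159
DEFAULT_HIGH_HZ = 5.0
DEFAULT_ORDER = 1
ANALYSIS_FS = 10.0

_COMMON_FS = (10.0, 100.0, 1000.0)


@dataclass
class RawRecording:
    """A raw single-channel recording with provenance metadata."""

    values: np.ndarray
    fs: float
    channel: str = "scr"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty recording")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.fs not in _COMMON_FS:
            warnings.warn(
                f"unusual sampling rate {self.fs} Hz (expected one of {_COMMON_FS})",
                stacklevel=2,
            )

    def to_signal(self) -> ScSignal:
        return ScSignal(self.values, self.fs)


def read_recording(path, fs: float, fmt: str | None = None, column: str | None = None) -> RawRecording:
    """Read a recording from single-column text or CSV/TSV.

    ``fmt`` is inferred from the suffix when omitted (``.csv``/``.tsv``
    delimited, anything else single-column). For delimited files,
    ``column`` names the conductance column (default: first column).
    Non-numeric rows raise a parse error naming the line.
    """
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "tsv" if path.endswith(".tsv") else "txt"
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        if df.shape[0] == 0:
            raise ValueError(f"{path}: empty input file")
        col = column if column is not None else df.columns[0]
        if col not in df.columns:
            raise KeyError(f"{path}: no column {col!r}")
        raw = df[col]
        values = pd.to_numeric(raw, errors="coerce").to_numpy()
        bad = np.nonzero(~np.isfinite(values))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[bad[0]]!r} at data line {bad[0] + 1}"
            )
        label = str(col)
    else:
        values_list = []
        with open(path) as fh:
            lineno = 0
            for line in fh:
                lineno += 1
                s = line.strip()
                if not s:
                    continue
                try:
                    values_list.append(float(s))
                except ValueError:
                    raise ValueError(f"{path}: non-numeric value {s!r} at line {lineno}") from None
        if not values_list:
            raise ValueError(f"{path}: empty input file")
        values = np.asarray(values_list)
        label = "scr"
    return RawRecording(values=values, fs=fs, channel=label, meta={"path": path, "format": fmt})


def bandpass(
    rec: RawRecording,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> RawRecording:
    """Causal Butterworth band-pass, cascaded high-pass then low-pass.

    The cascade is numerically safer than a single band-pass design at
    this extreme cutoff ratio (0.0159 Hz vs 5 Hz). A high cutoff at or
    above Nyquist is clipped just below it with a warning.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < nyq:
        raise ValueError(f"low cutoff {low} Hz outside (0, Nyquist)")
    if high >= nyq:
        high = 0.99 * nyq
        warnings.warn(
            f"high cutoff clipped to {high:.3g} Hz (below Nyquist {nyq:g} Hz)",
            stacklevel=2,
        )
    sos_hp = sps.butter(order, low, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = sps.butter(order, high, btype="lowpass", fs=rec.fs, output="sos")
    y = sps.sosfilt(sos_lp, sps.sosfilt(sos_hp, rec.values))
    return RawRecording(y, rec.fs, rec.channel, {**rec.meta, "bandpass": (low, high, order)})


def downsample_to_10hz(rec: RawRecording) -> RawRecording:
    """Decimate to the 10 Hz analysis grid by keeping every k-th sample.

    The preceding 5 Hz low-pass acts as the anti-alias filter. The
    sampling rate must be an integer multiple of 10 Hz; otherwise an
    explicit resampling step is required first.
    """
    k = rec.fs / ANALYSIS_FS
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"sampling rate {rec.fs} Hz is not an integer multiple of 10 Hz; "
            "resample explicitly before analysis"
        )
    k = int(round(k))
    if k == 1:
        return rec
    return RawRecording(
        rec.values[::k], ANALYSIS_FS, rec.channel, {**rec.meta, "decimated_from": rec.fs}
    )


def preprocess(rec: RawRecording, low=DEFAULT_LOW_HZ, high=DEFAULT_HIGH_HZ, order=DEFAULT_ORDER) -> ScSignal:
    """Band-pass filter and decimate a raw recording to the analysis grid."""
    return downsample_to_10hz(bandpass(rec, low, high, order)).to_signal()
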