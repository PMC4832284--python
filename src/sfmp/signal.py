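"""Uniformly sampled skin-conductance signal container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScSignal:
    """A uniformly sampled skin-conductance (or residual) trace.

    Parameters
    ----------
    values : array-like
        Samples in microsiemens (µS) for conductance data, or SN units
        for sudomotor-nerve drive signals.
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float, optional
        Time offset (s) of the first sample relative to the recording
        origin. Default 0.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ScSignal values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("ScSignal must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ScSignal values must all be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Window length in seconds (n_samples / fs)."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0 + k/fs``."""
        return self.t0 + np.arange(self.values.size) / self.fs
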