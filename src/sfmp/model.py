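"""Model/Results interface for matching-pursuit SF estimation.

:class:`SFMatchingPursuit` binds one preprocessed skin-conductance trace
to the forward model and search configuration; :meth:`~SFMatchingPursuit.fit`
runs dictionary construction, the greedy search, amplitude re-estimation
and above-threshold counting, returning an :class:`SFResults` with the
estimates, diagnostics, a text summary and a plot method.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dictionary import Dictionary, build_dictionary
from .mp import MpConfig, MpResult, count_sf, mp_search, reestimate_amplitudes, report_sf_onsets
from .scrf import ScrfParams
from .signal import ScSignal


class SFMatchingPursuit:
    """Matching-pursuit model of spontaneous skin-conductance fluctuations.

    Parameters
    ----------
    data : ScSignal or array-like
        Skin-conductance trace in µS, already band-pass filtered and on
        the 10 Hz analysis grid (see :mod:`sfmp.preprocess`).
    fs : float, optional
        Sampling rate (Hz); required when ``data`` is a plain array.
    params : ScrfParams, optional
        Forward-model (SCRF) parameters; defaults are calibrated so unit
        SN amplitude maps to a 1 µS-peak fluctuation.
    config : MpConfig, optional
        Search configuration (stopping rules, amplitude threshold).
    conduction_delay : float, optional
        Constant delay (s) subtracted from SN onsets when reporting
        central SF-generation times. Default 0.
    dictionary : Dictionary, optional
        A prebuilt dictionary to reuse across traces with identical
        length, sampling rate and forward model (skips reconstruction).

    Examples
    --------
    >>> from sfmp import SFMatchingPursuit, simulate
    >>> trace, truth = simulate.simulate_trace(simulate.SimSpec(target_rate=4, seed=7))
    >>> res = SFMatchingPursuit(trace).fit()
    >>> int(res.sf_count) == len(truth.onsets)
    True
    """

    def __init__(
        self,
        data: ScSignal | Sequence[float] | np.ndarray,
        fs: float | None = None,
        params: ScrfParams | None = None,
        config: MpConfig | None = None,
        conduction_delay: float = 0.0,
        dictionary: Dictionary | None = None,
    ) -> None:
        if isinstance(data, ScSignal):
            self.data = data
        else:
            if fs is None:
                raise ValueError("fs is required when data is not an ScSignal")
            self.data = ScSignal(np.asarray(data, dtype=float), fs)
        self.params = params if params is not None else ScrfParams()
        self.config = config if config is not None else MpConfig()
        self.conduction_delay = conduction_delay
        if dictionary is not None and dictionary.atoms.shape[1] != len(self.data):
            raise ValueError("prebuilt dictionary does not match the data grid")
        self._dictionary = dictionary

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, column: str, fs: float, **kwargs
    ) -> "SFMatchingPursuit":
        """Build the model from one column of a DataFrame."""
        if column not in df.columns:
            raise KeyError(f"column {column!r} not in dataframe")
        return cls(np.asarray(df[column], dtype=float), fs=fs, **kwargs)

    @property
    def dictionary(self) -> Dictionary:
        """The overcomplete atom set for this trace (built lazily, cached)."""
        if self._dictionary is None:
            self._dictionary = build_dictionary(len(self.data), self.data.fs, self.params)
        return self._dictionary

    def fit(self) -> "SFResults":
        """Invert the trace: greedy search, then joint amplitude re-fit."""
        mp = mp_search(self.data, self.dictionary, self.config)
        if mp.n_iterations > 0:
            amps, info = reestimate_amplitudes(
                self.data, self.dictionary, mp.selected_onsets, return_info=True
            )
            mp.sf_onsets = info["onsets"]
            mp.reestimated_amplitudes = amps
            mp.rank_deficient = info["rank_deficient"]
        else:
            mp.sf_onsets = np.empty(0)
            mp.reestimated_amplitudes = np.empty(0)
        return SFResults(self, mp)


class SFResults:
    """Estimates and diagnostics from one matching-pursuit inversion.

    Attributes
    ----------
    sf_onsets : ndarray
        SN-burst onsets (s) of all identified fluctuations (unique,
        ascending), before conduction-delay correction.
    sf_amplitudes : ndarray
        Jointly re-estimated amplitudes (µS by calibration), aligned with
        ``sf_onsets``. May include sub-threshold or negative entries;
        those are never counted.
    sf_count, sf_rate_per_min : int, float
        Number of above-threshold fluctuations and per-minute rate — the
        tonic sympathetic arousal estimate.
    stop_reason : str
        Which stopping rule terminated the greedy search.
    """

    def __init__(self, model: SFMatchingPursuit, mp: MpResult) -> None:
        self.model = model
        self.mp = mp
        self.sf_onsets = mp.sf_onsets
        self.sf_amplitudes = mp.reestimated_amplitudes
        self.stop_reason = mp.stop_reason
        self.n_iterations = mp.n_iterations
        self.sf_count, self.sf_rate_per_min = count_sf(
            self.sf_amplitudes, model.config, model.data.duration
        )

    @property
    def above_threshold(self) -> np.ndarray:
        """Boolean mask of counted (above-threshold) fluctuations."""
        a = self.sf_amplitudes
        return (a >= self.model.config.amp_threshold) & (a > 0)

    @property
    def central_onsets(self) -> np.ndarray:
        """SF onsets corrected for neural conduction delay."""
        return report_sf_onsets(self.sf_onsets, self.model.conduction_delay)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Reconstruction of the trace from the re-estimated atom set."""
        if self.sf_onsets.size == 0:
            return np.zeros(len(self.model.data))
        d = self.model.dictionary
        idx = [int(np.argmin(np.abs(d.onsets - o))) for o in self.sf_onsets]
        return d.atoms[idx].T @ self.sf_amplitudes

    @property
    def resid(self) -> np.ndarray:
        """Data minus the re-estimated reconstruction."""
        return self.model.data.values - self.fittedvalues

    @property
    def residual_norm(self) -> float:
        """ℓ2 norm of the greedy search's final residual."""
        return float(np.linalg.norm(self.mp.residual.values))

    def to_frame(self) -> pd.DataFrame:
        """Per-fluctuation table: onset, central onset, amplitude, counted."""
        return pd.DataFrame(
            {
                "onset_s": self.sf_onsets,
                "central_onset_s": self.central_onsets,
                "amplitude_uS": self.sf_amplitudes,
                "counted": self.above_threshold,
            }
        )

    def summary(self) -> str:
        """Human-readable summary of the inversion."""
        m = self.model
        lines = [
            "Matching-pursuit SF inversion",
            "=" * 45,
            f"Samples:              {len(m.data)} @ {m.data.fs:g} Hz "
            f"({m.data.duration:.1f} s)",
            f"Dictionary atoms:     {len(m.dictionary)}",
            f"Iterations:           {self.n_iterations} (cap {self.mp.max_iter})",
            f"Stop reason:          {self.stop_reason}",
            f"Residual l2 norm:     {self.residual_norm:.4f} (eps {self.mp.eps:.4f})",
            f"Amplitude threshold:  {m.config.amp_threshold:g} uS",
            f"SF above threshold:   {self.sf_count}",
            f"SF rate:              {self.sf_rate_per_min:.2f} per min "
            "(tonic arousal estimate)",
        ]
        if self.mp.rank_deficient:
            lines.append("Note: rank-deficient atom set; minimum-norm amplitudes.")
        if self.sf_count:
            lines.append("-" * 45)
            lines.append("  onset(s)  amplitude(uS)")
            for o, a in zip(
                self.sf_onsets[self.above_threshold],
                self.sf_amplitudes[self.above_threshold],
            ):
                lines.append(f"  {o:8.1f}  {a:12.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable record of the result (one epoch)."""
        return {
            "count": int(self.sf_count),
            "rate_per_min": float(self.sf_rate_per_min),
            "onsets_s": [float(x) for x in self.sf_onsets[self.above_threshold]],
            "amplitudes_uS": [float(x) for x in self.sf_amplitudes[self.above_threshold]],
            "stop_reason": self.stop_reason,
            "n_iterations": int(self.n_iterations),
            "residual_norm": self.residual_norm,
        }

    def plot(self, ax=None):
        """Plot data, reconstruction and counted SF onsets."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = self.model.data.times
        ax.plot(t, self.model.data.values, color="k", lw=1, label="data")
        ax.plot(t, self.fittedvalues, color="0.6", lw=1, label="MP fit")
        for o in self.sf_onsets[self.above_threshold]:
            ax.axvline(o, color="C3", ls=":", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("skin conductance (µS)")
        ax.legend(loc="upper right", frameon=False)
        return ax
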