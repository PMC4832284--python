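"""Overcomplete dictionary of candidate skin-conductance fluctuations.

Every atom is the forward-model response to a unit-amplitude SN burst at
one candidate onset, restricted to the data window. Candidate onsets run
from 9 s before the window start to 1 s after the window end in steps of
0.1 s, so bursts whose responses only partially enter the window are
representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scrf import ScrfParams, _burst_response

#: Candidate-onset grid extends this far (s) before the data window.
ONSET_PRE = 9.0
#: ... and this far (s) past the data window.
ONSET_POST = 1.0
#: Candidate-onset spacing (s), the time resolution of the analysis grid.
ONSET_STEP = 0.1


@dataclass
class Dictionary:
    """The atom set searched by matching pursuit.

    Attributes
    ----------
    onsets : ndarray, shape (m,)
        SN-burst onset times (s), strictly increasing.
    atoms : ndarray, shape (m, n)
        One atom per onset, sampled on the data grid (n samples).
    norms : ndarray, shape (m,)
        ℓ2 norm of each atom over the data window; all positive.
    fs : float
        Sampling rate (Hz) of the data grid.
    """

    onsets: np.ndarray
    atoms: np.ndarray
    norms: np.ndarray
    fs: float

    def __len__(self) -> int:
        return self.onsets.size


def build_dictionary(
    n_samples: int, fs: float, params: ScrfParams | None = None
) -> Dictionary:
    """Build the overcomplete dictionary for a window of ``n_samples`` at ``fs``.

    Onsets span ``[-9, duration + 1]`` s in 0.1 s steps (for a 60 s window
    at 10 Hz: 701 onsets, -9.0, -8.9, ..., 61.0). Atoms with zero energy
    inside the window are dropped.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if params is None:
        params = ScrfParams()
    duration = n_samples / fs
    n_onsets = int(round((duration + ONSET_POST + ONSET_PRE) / ONSET_STEP)) + 1
    onsets = -ONSET_PRE + ONSET_STEP * np.arange(n_onsets)
    t = np.arange(n_samples) / fs
    # (m, n) response matrix: exact continuous-time response sampled on the
    # grid; broadcasting over onsets.
    atoms = np.empty((n_onsets, n_samples))
    for i, onset in enumerate(onsets):
        atoms[i] = _burst_response(
            t, onset, params.burst_sd_default, params.time_constants, params.gain_value
        )
    norms = np.linalg.norm(atoms, axis=1)
    keep = norms > 0
    return Dictionary(onsets=onsets[keep], atoms=atoms[keep], norms=norms[keep], fs=fs)
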