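"""Greedy matching-pursuit inversion of the skin-conductance forward model.

The algorithm decomposes a (high-pass filtered) skin-conductance trace
into a small set of dictionary atoms — candidate spontaneous fluctuations
(SF). On each iteration the atom with the largest signed correlation with
the current residual is selected and its optimal contribution subtracted.
Only positive contributions are accepted: negative SF are biophysically
impossible. Iteration stops when

* the residual ℓ2 norm falls below ``ε = sqrt(0.001 · N)`` (N samples), or
* the number of selected atoms reaches 30 per minute of data, or
* no atom with a positive contribution remains.

The stopping conditions are evaluated in that order after each pass, so a
pass that finds no positive atom still terminates (its coefficient is
never applied). Because overlapping SF make the greedy coefficients
misallocate amplitude between neighbours, all selected atoms are
subsequently re-fit jointly by multiple regression; the regression
weights are the final amplitude estimates, and the number of fluctuations
with amplitude at or above a threshold (0.1 µS recommended) per minute is
the tonic-sympathetic-arousal estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dictionary import Dictionary
from .signal import ScSignal

STOP_RESIDUAL = "residual_below_eps"
STOP_MAX_ITER = "max_iterations"
STOP_NONPOSITIVE = "nonpositive_coefficient"

# A selection whose cosine with the residual is below this explains less
# than ~1e-14 of the residual variance: an exact-arithmetic zero that
# floating point renders as a denormal-positive coefficient. Treated as
# nonpositive so applied iterations always strictly reduce the residual.
_COS_TOL = 1e-7


@dataclass
class MpConfig:
    """Tuning knobs of the matching-pursuit search.

    Parameters
    ----------
    eps_factor : float
        Residual stopping threshold is ``sqrt(eps_factor * N)`` for N data
        samples. Default 0.001.
    max_rate : float
        Maximum number of selected atoms per minute of data. Default 30
        (the fixed SF budget of the reference Bayesian inversion).
    amp_threshold : float
        Minimum re-estimated amplitude (µS) for an SF to be counted.
        Default 0.1 µS, the threshold with maximal predictive validity.
    normalize_argmax : bool
        If True (default), select the atom maximizing the norm-weighted
        signed correlation ``<g, R>/‖g‖`` — the classic matching-pursuit
        criterion, unbiased with respect to atom-norm differences near
        the window edges. If False, maximize the raw signed inner product
        ``<g, R>``. The subtracted coefficient is the optimal projection
        ``<g, R>/‖g‖²`` either way, so the residual never increases.
    """

    eps_factor: float = 0.001
    max_rate: float = 30.0
    amp_threshold: float = 0.1
    normalize_argmax: bool = True

    def __post_init__(self) -> None:
        if not self.eps_factor > 0:
            raise ValueError("eps_factor must be positive")
        if not self.max_rate > 0:
            raise ValueError("max_rate must be positive")
        if not self.amp_threshold >= 0:
            raise ValueError("amp_threshold must be nonnegative")

    def eps(self, n_samples: int) -> float:
        """Residual stopping threshold ε for a window of ``n_samples``."""
        return math.sqrt(self.eps_factor * n_samples)

    def max_iter(self, duration: float) -> int:
        """Selection cap: ``ceil(max_rate · duration/60)``."""
        return int(math.ceil(self.max_rate * duration / 60.0))


@dataclass
class MpResult:
    """Raw output of one matching-pursuit search.

    ``selected_onsets`` lists onsets in selection order (an onset may be
    selected more than once); ``greedy_coefficients`` are the per-pass
    applied coefficients, all positive. ``reestimated_amplitudes`` (and
    the matching ``sf_onsets``) are filled in by the regression step.
    """

    selected_onsets: np.ndarray
    greedy_coefficients: np.ndarray
    residual: ScSignal
    stop_reason: str
    n_iterations: int
    eps: float
    max_iter: int
    sf_onsets: np.ndarray | None = None
    reestimated_amplitudes: np.ndarray | None = None
    rank_deficient: bool = False


def mp_search(data: ScSignal, dictionary: Dictionary, cfg: MpConfig | None = None) -> MpResult:
    """Run the greedy search on one trace.

    ``data`` must be sampled on the dictionary's grid. Returns an
    :class:`MpResult` without re-estimated amplitudes.
    """
    if cfg is None:
        cfg = MpConfig()
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    if data.values.size != dictionary.atoms.shape[1]:
        raise ValueError(
            f"data length {data.values.size} does not match dictionary grid "
            f"({dictionary.atoms.shape[1]} samples)"
        )
    n = data.values.size
    eps = cfg.eps(n)
    max_iter = cfg.max_iter(data.duration)

    residual = data.values.copy()
    sel_idx: list[int] = []
    coeffs: list[float] = []
    stop = None
    while True:
        r_norm = float(np.linalg.norm(residual))
        corr = dictionary.atoms @ residual
        score = corr / dictionary.norms if cfg.normalize_argmax else corr
        j = int(np.argmax(score))  # ties: first (earliest onset) wins
        a = corr[j] / dictionary.norms[j] ** 2
        applied = corr[j] > _COS_TOL * dictionary.norms[j] * r_norm
        if applied:
            residual -= a * dictionary.atoms[j]
            sel_idx.append(j)
            coeffs.append(float(a))
        # stopping conditions, in the documented order
        if np.linalg.norm(residual) < eps:
            stop = STOP_RESIDUAL
            break
        if len(sel_idx) >= max_iter:
            stop = STOP_MAX_ITER
            break
        if not applied:
            stop = STOP_NONPOSITIVE
            break

    return MpResult(
        selected_onsets=dictionary.onsets[sel_idx],
        greedy_coefficients=np.asarray(coeffs),
        residual=ScSignal(residual, data.fs, data.t0),
        stop_reason=stop,
        n_iterations=len(sel_idx),
        eps=eps,
        max_iter=max_iter,
    )


def reestimate_amplitudes(
    data: ScSignal,
    dictionary: Dictionary,
    selected_onsets: Sequence[float],
    return_info: bool = False,
):
    """Jointly re-fit the amplitudes of the selected atoms by least squares.

    Duplicate onsets are merged into a single predictor. The regression
    has no intercept: baseline is assumed removed by the high-pass
    preprocessing, and atoms model fluctuations, not level. Rank-deficient
    atom sets are solved by the minimum-norm solution and flagged.

    Returns the weight vector aligned with ``numpy.unique(selected_onsets)``;
    with ``return_info=True`` also a dict carrying the unique onsets and a
    rank-deficiency flag.
    """
    onsets = np.unique(np.asarray(selected_onsets, dtype=float))
    if onsets.size < 1:
        raise ValueError("at least one selected onset is required")
    idx = []
    for o in onsets:
        j = int(np.argmin(np.abs(dictionary.onsets - o)))
        if abs(dictionary.onsets[j] - o) > 1e-9:
            raise ValueError(f"onset {o} is not on the dictionary grid")
        idx.append(j)
    X = dictionary.atoms[idx].T  # (n_samples, n_atoms)
    w, _, rank, _ = np.linalg.lstsq(X, data.values, rcond=None)
    rank_deficient = rank < X.shape[1]
    if return_info:
        return w, {"onsets": onsets, "rank_deficient": rank_deficient}
    return w


def count_sf(
    amplitudes: Sequence[float], cfg: MpConfig | None = None, duration: float = 60.0
) -> tuple[int, float]:
    """Count above-threshold SF and convert to a per-minute rate.

    An SF is counted when its re-estimated amplitude is positive and at
    least ``cfg.amp_threshold`` (so a zero threshold counts exactly the
    positive amplitudes). Returns ``(count, rate_per_min)``.
    """
    if cfg is None:
        cfg = MpConfig()
    if not duration > 0:
        raise ValueError("duration must be positive")
    a = np.asarray(amplitudes, dtype=float)
    count = int(np.sum((a >= cfg.amp_threshold) & (a > 0)))
    return count, count / (duration / 60.0)


def report_sf_onsets(
    selected_onsets: Sequence[float], conduction_delay: float = 0.0
) -> np.ndarray:
    """Convert SN-burst onsets to central SF-generation times.

    The peripheral model carries no conduction delay; when the time of
    central generation is wanted, a constant delay is subtracted from the
    SN-burst latency estimates. Default delay 0 (onsets pass through).
    """
    if conduction_delay < 0:
        raise ValueError("conduction_delay must be nonnegative")
    return np.asarray(selected_onsets, dtype=float) - conduction_delay
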