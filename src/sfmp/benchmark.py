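"""Scoring of inversion output against simulated ground truth.

Estimated fluctuations are matched to true bursts greedily by time:
among all unpaired (true, estimated) combinations, the pair with the
smallest absolute onset difference is committed first, each item at most
once, until the smaller side is exhausted. Count, amplitude and onset
accuracy are then summarized as root-mean-squared errors, amplitude and
onset over matched pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class MatchResult:
    """Greedy nearest-in-time pairing of true and estimated fluctuations.

    ``pairs`` holds ``(true_index, est_index, time_diff)`` with signed
    ``time_diff = est - true`` (s); indices refer to the *sorted* onset
    lists. Exactly ``min(n_true, n_est)`` pairs are formed.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_true: list[int]
    unmatched_est: list[int]


def greedy_match(true_onsets: Sequence[float], est_onsets: Sequence[float]) -> MatchResult:
    """Pair estimated with true onsets, smallest absolute time difference first.

    Ties in |Δt| are broken by the earlier true onset, then the earlier
    estimated onset (a deterministic convention).
    """
    t = np.sort(np.asarray(true_onsets, dtype=float))
    e = np.sort(np.asarray(est_onsets, dtype=float))
    cand = sorted(
        ((abs(e[j] - t[i]), t[i], e[j], i, j) for i in range(t.size) for j in range(e.size)),
    )
    used_t = np.zeros(t.size, dtype=bool)
    used_e = np.zeros(e.size, dtype=bool)
    pairs = []
    for _, _, _, i, j in cand:
        if used_t[i] or used_e[j]:
            continue
        used_t[i] = used_e[j] = True
        pairs.append((i, j, float(e[j] - t[i])))
        if len(pairs) == min(t.size, e.size):
            break
    return MatchResult(
        pairs=pairs,
        unmatched_true=[i for i in range(t.size) if not used_t[i]],
        unmatched_est=[j for j in range(e.size) if not used_e[j]],
    )


def _rmse(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("RMSE of an empty set is undefined")
    return float(np.sqrt(np.mean(x**2)))


def rmse_counts(true_counts: Sequence[int], est_counts: Sequence[int]) -> float:
    """RMSE between true and estimated SF numbers across traces."""
    t = np.asarray(true_counts, dtype=float)
    e = np.asarray(est_counts, dtype=float)
    if t.shape != e.shape:
        raise ValueError("count vectors must have equal length")
    return _rmse(e - t)


def rmse_onset(match: MatchResult) -> float:
    """RMSE of onset differences over matched pairs (unmatched ignored)."""
    return _rmse([d for _, _, d in match.pairs])


def rmse_amplitude(
    true_amps: Sequence[float], est_amps: Sequence[float], match: MatchResult
) -> float:
    """RMSE of amplitude differences over matched pairs (unmatched ignored).

    ``true_amps``/``est_amps`` must be aligned with the *sorted* onset
    lists given to :func:`greedy_match`.
    """
    ta = np.asarray(true_amps, dtype=float)
    ea = np.asarray(est_amps, dtype=float)
    return _rmse([ea[j] - ta[i] for i, j, _ in match.pairs])


def benchmark_corpus(corpus, params=None, config=None) -> pd.DataFrame:
    """Invert every trace of a simulated corpus and score it per bin.

    ``corpus`` maps true burst count -> list of (signal, truth) as
    produced by :func:`sfmp.simulate.generate_corpus`. Returns one row
    per bin with columns ``n_true, n_traces, mean_est, rmse_count,
    rmse_amp, rmse_onset`` (amplitude/onset pooled over all matched
    pairs of the bin). A single dictionary is reused across traces.
    """
    from .model import SFMatchingPursuit

    rows = []
    shared = None
    for n_true in sorted(corpus):
        traces = corpus[n_true]
        est_counts, amp_sq, ons_sq = [], [], []
        for signal, truth in traces:
            model = SFMatchingPursuit(
                signal, params=params, config=config, dictionary=shared
            )
            shared = model.dictionary
            res = model.fit()
            est_counts.append(res.sf_count)
            mask = res.above_threshold
            est_on = res.sf_onsets[mask]
            est_am = res.sf_amplitudes[mask]
            order_t = np.argsort(truth.onsets)
            m = greedy_match(truth.onsets, est_on)
            for i, j, d in m.pairs:
                amp_sq.append((est_am[j] - truth.amplitudes[order_t][i]) ** 2)
                ons_sq.append(d**2)
        rows.append(
            {
                "n_true": n_true,
                "n_traces": len(traces),
                "mean_est": float(np.mean(est_counts)),
                "rmse_count": rmse_counts([n_true] * len(traces), est_counts),
                "rmse_amp": float(np.sqrt(np.mean(amp_sq))) if amp_sq else np.nan,
                "rmse_onset": float(np.sqrt(np.mean(ons_sq))) if ons_sq else np.nan,
            }
        )
    return pd.DataFrame(rows)
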