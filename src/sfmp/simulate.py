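"""Synthetic skin-conductance data under the generative model.

Traces emulate the benchmark protocol: 60-s windows at 10 Hz containing
1–30 sudomotor bursts. Burst onsets follow a homogeneous Poisson process
with a 1-s refractory period (exponential inter-burst intervals with mean
equal to the reciprocal of the target per-minute rate, plus 1 s), burst
amplitudes are uniform on [0.1, 2.0] SN units, and each burst train is
rendered through the peripheral forward model. Traces are noiseless by
design: the benchmark isolates inversion error from measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scrf import ScrfParams, SnBurst, simulate_sc
from .signal import ScSignal


@dataclass
class SimSpec:
    """Conditions of one simulated trace.

    ``target_rate`` is the desired burst frequency per minute; the
    realized count in a 60-s window is random and typically a little
    lower because of the refractory second added to every interval.
    """

    duration: float = 60.0
    fs: float = 10.0
    burst_sd: float = 0.3
    amp_low: float = 0.1
    amp_high: float = 2.0
    refractory: float = 1.0
    target_rate: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.amp_low < self.amp_high:
            raise ValueError("amp_low must be below amp_high")
        if self.refractory < 0:
            raise ValueError("refractory must be nonnegative")
        if not self.target_rate >= 1:
            raise ValueError("target_rate must be >= 1 per minute")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")


@dataclass
class GroundTruth:
    """True burst train behind a simulated trace (onsets sorted, s)."""

    onsets: np.ndarray
    amplitudes: np.ndarray


def draw_onsets(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw burst-onset times for one window.

    Inter-burst intervals are ``Exponential(mean = 60/target_rate s) +
    refractory``, accumulated from the window start; the first onset is
    one interval from t = 0. Every gap is therefore at least the
    refractory period. Onsets at or beyond ``duration`` are discarded.
    """
    mean = 60.0 / spec.target_rate
    onsets = []
    t = 0.0
    while True:
        t += rng.exponential(mean) + spec.refractory
        if t >= spec.duration:
            break
        onsets.append(t)
    return np.asarray(onsets)


def draw_amplitudes(n: int, spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` burst amplitudes, uniform on [amp_low, amp_high]."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return rng.uniform(spec.amp_low, spec.amp_high, size=n)


def render(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    spec: SimSpec,
    params: ScrfParams | None = None,
) -> ScSignal:
    """Pass a burst train through the forward model."""
    bursts = [
        SnBurst(onset=float(o), amplitude=float(a), sd=spec.burst_sd)
        for o, a in zip(onsets, amplitudes)
    ]
    return simulate_sc(bursts, params, duration=spec.duration, fs=spec.fs)


def simulate_trace(
    spec: SimSpec | None = None,
    params: ScrfParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ScSignal, GroundTruth]:
    """Simulate one trace; returns the signal and its ground truth.

    The random stream is consumed in a documented order — onsets first,
    then amplitudes — so corpora are bitwise reproducible from a seed.
    """
    if spec is None:
        spec = SimSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    onsets = draw_onsets(spec, rng)
    amps = draw_amplitudes(onsets.size, spec, rng)
    return render(onsets, amps, spec, params), GroundTruth(onsets=onsets, amplitudes=amps)


def generate_corpus(
    n_per_bin: int,
    bins,
    spec: SimSpec | None = None,
    params: ScrfParams | None = None,
    rng: np.random.Generator | None = None,
    rate_sweep=range(1, 31),
    max_draws: int | None = None,
) -> dict[int, list[tuple[ScSignal, GroundTruth]]]:
    """Generate ``n_per_bin`` traces for every requested burst-count bin.

    Target rates from ``rate_sweep`` (default 1–30 per minute) are cycled;
    each drawn onset sequence is assigned to the bin equal to its realized
    burst count and kept if that bin is requested and not yet full.
    Amplitudes are drawn, and the trace rendered, only for kept sequences.

    For the full benchmark replication ``n_per_bin=1000``; smaller values
    give scaled-down corpora with the same per-trace conditions.

    Raises
    ------
    RuntimeError
        If ``max_draws`` onset sequences (default ``4000 * n_per_bin *
        n_bins``) are exhausted before some bin fills; the message names
        the unreachable bin(s).
    """
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    bins = [int(b) for b in bins]
    if spec is None:
        spec = SimSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if max_draws is None:
        max_draws = 4000 * n_per_bin * len(bins)
    rates = list(rate_sweep)
    corpus: dict[int, list] = {b: [] for b in bins}
    draws = 0
    ri = 0
    while any(len(v) < n_per_bin for v in corpus.values()):
        if draws >= max_draws:
            missing = [b for b, v in corpus.items() if len(v) < n_per_bin]
            raise RuntimeError(
                f"could not fill burst-count bin(s) {missing} within "
                f"{max_draws} draws; unreachable under these conditions"
            )
        rate = rates[ri % len(rates)]
        ri += 1
        draws += 1
        trial = SimSpec(
            duration=spec.duration,
            fs=spec.fs,
            burst_sd=spec.burst_sd,
            amp_low=spec.amp_low,
            amp_high=spec.amp_high,
            refractory=spec.refractory,
            target_rate=rate,
        )
        onsets = draw_onsets(trial, rng)
        k = onsets.size
        if k in corpus and len(corpus[k]) < n_per_bin:
            amps = draw_amplitudes(k, trial, rng)
            corpus[k].append(
                (render(onsets, amps, trial, params), GroundTruth(onsets, amps))
            )
    return corpus
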