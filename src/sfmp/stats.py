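"""Predictive-validity statistics for arousal estimates.

A method's ability to separate two known psychological states is cast as
a model comparison: a general linear model with the condition contrast as
the response variable and the estimated tonic arousal as predictor (plus
an intercept, and subject effects for within-subject designs). The
residual sum of squares RSS maps to a negative log likelihood

    NLL = n · log(RSS / n)

so that, at fixed n and model complexity, a smaller NLL means higher
predictive validity. The log Bayes factor LBF between a method and a
reference is the difference of their NLLs; |LBF| > 3 is conventionally
decisive (1/exp(3) ≤ .05). The t statistic for the arousal coefficient in
these GLMs equals the classic paired (within-subject) or independent-
samples (between-subject) t test, and method rankings by NLL and by |t|
coincide on a fixed design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

#: |LBF| above which a model comparison is conventionally decisive.
DECISIVE_LBF = 3.0


@dataclass
class ContrastResult:
    """GLM contrast of estimated arousal between two conditions."""

    rss: float
    n: int
    nll: float
    t_stat: float
    dof: int
    lbf_vs_reference: float | None = None

    @property
    def decisive(self) -> bool | None:
        if self.lbf_vs_reference is None:
            return None
        return abs(self.lbf_vs_reference) > DECISIVE_LBF


def nll_from_rss(rss: float, n: int) -> float:
    """Negative log likelihood ``n log(rss/n)`` of a least-squares fit."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0:
        raise ZeroDivisionError("rss = 0: degenerate (perfect) fit, NLL = -inf")
    return n * math.log(rss / n)


def lbf(nll_method, nll_reference) -> float:
    """Log Bayes factor of a method against a reference.

    Accepts plain NLL values or :class:`ContrastResult` objects; results
    must come from the same observations, so mismatched ``n`` is an
    error. Negative LBF favors the method over the reference.
    """
    if isinstance(nll_method, ContrastResult) and isinstance(nll_reference, ContrastResult):
        if nll_method.n != nll_reference.n:
            raise ValueError(
                f"NLL comparison requires identical n "
                f"({nll_method.n} vs {nll_reference.n})"
            )
        return nll_method.nll - nll_reference.nll
    return float(nll_method) - float(nll_reference)


def is_decisive(lbf_value: float) -> bool:
    """Whether an LBF magnitude exceeds the conventional cutoff of 3."""
    return abs(lbf_value) > DECISIVE_LBF


def _fit_contrast(y: np.ndarray, Z: np.ndarray, sa: np.ndarray) -> tuple[float, float, int]:
    """Fit ``y ~ Z + sa`` by OLS; return (rss, t of sa coefficient, dof).

    When the arousal predictor ``sa`` lies in the span of the nuisance
    columns ``Z`` (e.g. identical conditions under subject effects), its
    coefficient is unidentifiable and carries no association: t is 0 by
    convention and the RSS is that of the nuisance-only model.
    """
    sa_res = sa - Z @ np.linalg.lstsq(Z, sa, rcond=None)[0]
    if np.linalg.norm(sa_res) <= 1e-10 * (1.0 + np.linalg.norm(sa)):
        res = sm.OLS(y, Z).fit()
        return float(res.ssr), 0.0, int(res.df_resid) - 1
    res = sm.OLS(y, np.column_stack([Z, sa])).fit()
    return float(res.ssr), float(res.tvalues[-1]), int(res.df_resid)


def paired_contrast(
    values_cond_a: Sequence[float], values_cond_b: Sequence[float]
) -> ContrastResult:
    """Within-subject contrast of arousal between two conditions.

    ``values_cond_a``/``values_cond_b`` are per-subject arousal estimates
    in the two conditions, same subject order. The GLM regresses the
    condition code on the estimates with subject dummy effects; its
    t statistic equals the paired t test on the differences, with
    n_subjects - 1 degrees of freedom.
    """
    a = np.asarray(values_cond_a, dtype=float)
    b = np.asarray(values_cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired contrast needs two equal-length 1-d arrays")
    ns = a.size
    if ns < 2:
        raise ValueError("at least two subjects are required")
    sa = np.concatenate([a, b])
    if np.ptp(sa) == 0:
        raise ValueError("degenerate input: no variance in arousal estimates")
    cond = np.concatenate([np.zeros(ns), np.ones(ns)])
    subj = np.tile(np.eye(ns), (2, 1))[:, 1:]  # ns-1 dummies; intercept separate
    Z = np.column_stack([np.ones(2 * ns), subj])
    rss, t, dof = _fit_contrast(cond, Z, sa)
    return ContrastResult(rss=rss, n=2 * ns, nll=nll_from_rss(rss, 2 * ns), t_stat=t, dof=dof)


def independent_contrast(
    group_a_diffs: Sequence[float], group_b_diffs: Sequence[float]
) -> ContrastResult:
    """Between-subject contrast of per-participant arousal differences.

    Each argument holds one group's treatment-minus-rest arousal
    differences. The GLM regresses the group code on the differences with
    an intercept; its t statistic equals the equal-variance independent-
    samples t test, with n_a + n_b - 2 degrees of freedom.
    """
    a = np.asarray(group_a_diffs, dtype=float)
    b = np.asarray(group_b_diffs, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two participants")
    sa = np.concatenate([a, b])
    if np.ptp(sa) == 0:
        raise ValueError("degenerate input: no variance in arousal differences")
    grp = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    Z = np.ones((sa.size, 1))
    rss, t, dof = _fit_contrast(grp, Z, sa)
    n = sa.size
    return ContrastResult(rss=rss, n=n, nll=nll_from_rss(rss, n), t_stat=t, dof=dof)


def treatment_minus_rest(table, subject="subject", condition="condition", value="rate_per_min",
                         treatment="treatment", rest="rest"):
    """Per-participant treatment-minus-rest differences from a long table.

    Participants missing either epoch are dropped. Returns a pandas
    Series indexed by subject.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
    if treatment not in wide.columns or rest not in wide.columns:
        raise ValueError(f"conditions {treatment!r}/{rest!r} not found")
    wide = wide.dropna(subset=[treatment, rest])
    return wide[treatment] - wide[rest]
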