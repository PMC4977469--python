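"""qPCR relative quantification and induction-outcome correlation.

Quantification follows the comparative-Ct convention with a housekeeping
reference gene (GAPDH in the motivating experiments):

    dCt(gene)   = mean Ct(reference) - mean Ct(gene)     per sample group
    ddCt        = dCt(condition A) - dCt(condition B)    = log2 fold change
    linear fold = 2 ** ddCt

A gene's induction time-course is its fold change versus its own time-0
level; the maximal induction within an early window (72 h by default in the
analyses this package supports) is the early predictor correlated against
the final differentiation outcome with a one-tailed Pearson test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtTable

logger = logging.getLogger(__name__)


def delta_ct(ct_table: CtTable, group: str) -> pd.Series:
    """Per-gene dCt (log2 expression relative to the reference gene) within
    one sample group.

    Non-finite Ct values (undetermined wells) are excluded with a logged
    warning; a gene whose replicates are all excluded is an error.
    """
    samples = ct_table.design.samples_for(group)
    block = ct_table.values[samples].to_numpy(dtype=float)
    finite = np.isfinite(block)
    if not finite.all():
        logger.warning(
            "group %r: excluded %d non-finite Ct wells", group, int((~finite).sum())
        )
    if (~finite).all(axis=1).any():
        bad = ct_table.values.index[(~finite).all(axis=1)]
        raise ValueError(f"group {group!r}: all Ct replicates non-finite for {list(bad)}")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(finite, block, np.nan), axis=1)
    means = pd.Series(means, index=ct_table.values.index)
    ref = means[ct_table.reference_gene]
    if not math.isfinite(ref):
        raise ValueError(f"group {group!r}: reference gene mean Ct is not finite")
    return ref - means


def ddct_log2fc(delta_ct_a: pd.Series | float, delta_ct_b: pd.Series | float):
    """ddCt = dCt(a) - dCt(b): the log2 fold change of group a over group b.

    Returns ``(log2fc, linear_fold)``; antisymmetric in its arguments.
    """
    log2fc = delta_ct_a - delta_ct_b
    return log2fc, 2.0 ** log2fc


@dataclass
class InductionSeries:
    """Fold-change time-course of one gene relative to its time-0 level."""

    gene: str
    times: list[float]
    folds: list[float]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.folds):
            raise ValueError("times and folds must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(f <= 0 for f in self.folds):
            raise ValueError("fold changes must be positive")


def max_induction(series: InductionSeries, window_end_hours: float) -> tuple[float, float]:
    """Maximal linear fold change within [0, window]; returns (fold, time)."""
    in_window = [(f, t) for t, f in zip(series.times, series.folds) if t <= window_end_hours]
    if not in_window:
        raise ValueError(
            f"no time points within [0, {window_end_hours}] h for {series.gene}"
        )
    fold, time = max(in_window, key=lambda ft: ft[0])
    return fold, time


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    p_one_tailed: float


def correlate_induction(
    max_inductions, outcome_proportions, tail: str = "upper"
) -> CorrelationResult:
    """Pearson correlation between maximal inductions and outcomes with a
    one-tailed t-test (default: testing positive association).

    t = r sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom; at
    r = 0 the upper-tail p is exactly 0.5; |r| = 1 is the collinear limit
    with p reported as 0.
    """
    x = np.asarray(max_inductions, dtype=float)
    y = np.asarray(outcome_proportions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = math.inf * np.sign(r)
        p_upper = 0.0 if r > 0 else 1.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p_upper = float(stats.t.sf(t, df))
    if tail == "upper":
        p = p_upper
    elif tail == "two-sided":
        p = float(min(2 * min(p_upper, 1 - p_upper), 1.0))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return CorrelationResult(r, n, float(t), p)
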