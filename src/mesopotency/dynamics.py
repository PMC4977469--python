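"""Regulation-dynamics classification, profile clustering and the
expression/methylation association test.

Regulation is described by a gene's log2 fold changes against the baseline
condition in the two non-baseline conditions (``fc_mid``: the intermediate
platform, ``fc_high``: the most efficient platform). Classes follow the
magnitude-and-sign convention of the study design:

* increased  - same sign, the later value is farther from zero
* decreased  - same sign, the later value is closer to zero
* reversed   - the sign flips
* unchanged  - neither, within the tolerance

A separate monotone-trend call (increasing/decreasing/other across
baseline -> mid -> high) picks out genes tracking the differentiation
efficiency ranking of the platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


def _sign_with_tol(value: float, other: float, tol: float) -> int:
    """Sign of ``value``; a value within +/-tol of 0 inherits the other's sign."""
    if abs(value) > tol:
        return 1 if value > 0 else -1
    if abs(other) > tol:
        return 1 if other > 0 else -1
    return 0


def classify_regulation(fc_mid: float, fc_high: float, tol: float = 0.0) -> str:
    """Classify the mid -> high transition of a gene's regulation.

    Total function of (fc_mid, fc_high) given ``tol``; a value within
    +/-tol of zero is treated as carrying the sign of the other value, so a
    profile like (0.12, 2.17) counts as increased rather than reversed.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    s_mid = _sign_with_tol(fc_mid, fc_high, tol)
    s_high = _sign_with_tol(fc_high, fc_mid, tol)
    if s_mid == 0 and s_high == 0:
        return "unchanged"
    if s_mid != s_high and abs(fc_mid) > tol and abs(fc_high) > tol:
        return "reversed"
    if abs(fc_high) > abs(fc_mid) + tol:
        return "increased"
    if abs(fc_high) < abs(fc_mid) - tol:
        return "decreased"
    return "unchanged"


def classify_trend(fc_mid: float, fc_high: float, tol: float = 0.0) -> str:
    """Monotone trend across baseline -> mid -> high (baseline fc is 0)."""
    if fc_mid >= -tol and fc_high >= fc_mid - tol and fc_high > tol:
        return "monotone-increasing"
    if fc_mid <= tol and fc_high <= fc_mid + tol and fc_high < -tol:
        return "monotone-decreasing"
    return "other"


# ---------------------------------------------------------------------------
# k-means with dot-product similarity
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Assignments, centroids and the per-iteration objective trace."""

    assignments: pd.Series
    centroids: np.ndarray
    objective_trace: list[float]
    n_iter: int


def kmeans_dot(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    metric: str = "dot",
) -> ClusterResult:
    """Lloyd-style k-means assigning each profile to the centroid of maximal
    dot-product similarity (``metric='cosine'`` normalizes centroids first).

    Centroids are arithmetic means of their members; empty clusters are
    re-seeded from the point most dissimilar to its current centroid. Because
    the mean update does not always increase the un-normalized dot-product
    objective, iteration additionally stops (keeping the previous state) if
    the objective would decrease, so the reported objective trace is
    non-decreasing. Deterministic under ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = profiles.to_numpy(dtype=float)
    unique_rows = np.unique(x, axis=0)
    if unique_rows.shape[0] < k:
        raise ValueError(f"fewer distinct profiles ({unique_rows.shape[0]}) than k={k}")
    rng = np.random.default_rng(seed)
    centroids = unique_rows[rng.choice(unique_rows.shape[0], size=k, replace=False)]

    def similarity(c: np.ndarray) -> np.ndarray:
        if metric == "cosine":
            norms = np.linalg.norm(c, axis=1)
            norms[norms == 0] = 1.0
            return x @ (c / norms[:, None]).T
        return x @ c.T

    assign = np.full(x.shape[0], -1)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sim = similarity(centroids)
        new_assign = sim.argmax(axis=1)
        objective = float(sim[np.arange(len(x)), new_assign].sum())
        if trace and objective < trace[-1]:
            n_iter -= 1
            break
        trace.append(objective)
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
        new_centroids = centroids.copy()
        own_sim = sim[np.arange(len(x)), assign]
        for j in range(k):
            members = assign == j
            if members.any():
                new_centroids[j] = x[members].mean(axis=0)
            else:
                new_centroids[j] = x[own_sim.argmin()]
        centroids = new_centroids
    assignments = pd.Series(assign, index=profiles.index, name="cluster")
    return ClusterResult(assignments, centroids, trace, n_iter)


# ---------------------------------------------------------------------------
# probe consistency and association
# ---------------------------------------------------------------------------

def probe_consistency(
    gene: str,
    probe_delta_betas: list[float],
    min_delta: float = 0.15,
    exclusions: set[str] | list[str] = ("GNAS",),
) -> bool:
    """Do a gene's substantial methylation probes agree in direction?

    Only probes with ``|delta beta| > min_delta`` are considered; a gene is
    consistent iff all of them share one sign. Genes on the exclusion list
    (the GNAS complex locus by default, whose probes are known to disagree)
    are consistent by fiat, as are genes with at most one qualifying probe.
    """
    if not (0 <= min_delta <= 1):
        raise ValueError("min_delta must lie in [0, 1]")
    if gene in set(exclusions):
        return True
    qualifying = [d for d in probe_delta_betas if abs(d) > min_delta]
    if len(qualifying) <= 1:
        return True
    return all(d > 0 for d in qualifying) or all(d < 0 for d in qualifying)


@dataclass
class AssociationResult:
    """2x2 association between an expression class and a methylation class."""

    table: np.ndarray
    odds_ratio: float
    p_value: float
    degenerate: bool = False


def dynamics_association(
    expr_class_members: set[str],
    meth_class_members: set[str],
    background: set[str],
) -> AssociationResult:
    """Two-sided Fisher exact test of class co-membership over a background.

    The background is the set of genes measured on both platforms; both
    classes must be subsets of it. Degenerate tables (an empty class or a
    class equal to the background) return p = 1 with an undefined (NaN) odds
    ratio and the ``degenerate`` flag set.
    """
    expr = set(expr_class_members)
    meth = set(meth_class_members)
    bg = set(background)
    if expr - bg:
        raise ValueError(f"expression class members outside background: {sorted(expr - bg)[:5]}")
    if meth - bg:
        raise ValueError(f"methylation class members outside background: {sorted(meth - bg)[:5]}")
    a = len(expr & meth)
    b = len(expr - meth)
    c = len(meth - expr)
    d = len(bg) - a - b - c
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return AssociationResult(table, float("nan"), 1.0, degenerate=True)
    odds_ratio, p_value = fisher_exact(table, alternative="two-sided")
    return AssociationResult(table, float(odds_ratio), float(p_value), degenerate=False)
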