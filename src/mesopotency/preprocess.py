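"""Detection filtering, quantile normalization, probe collapsing and
baseline log2 fold changes.

Arrays are compared on the log2 scale throughout: after quantile
normalization every sample column carries the identical multiset of values
(the row-wise mean of the per-column order statistics), and fold changes are
simple differences of per-condition means against the named baseline
condition (the culture platform with zero cardiomyogenesis efficiency in the
motivating design).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import DesignError, ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_detection(
    raw: ExpressionMatrix,
    detection_pvals: pd.DataFrame,
    threshold: float = 0.05,
    mode: str = "any",
) -> ExpressionMatrix:
    """Drop probes not reliably detected above background.

    A probe is retained iff its detection p-value passes ``threshold`` in at
    least one sample (``mode='any'``, the default, matching common Illumina
    practice) or in every sample (``mode='all'``, the strict alternative).
    """
    if detection_pvals.shape != raw.values.shape:
        raise ValueError(
            f"detection table shape {detection_pvals.shape} != matrix shape {raw.values.shape}"
        )
    det = detection_pvals.reindex(index=raw.values.index, columns=raw.values.columns)
    passed = det.to_numpy(dtype=float) <= threshold
    if mode == "any":
        keep = passed.any(axis=1)
    elif mode == "all":
        keep = passed.all(axis=1)
    else:
        raise ValueError(f"unknown detection mode {mode!r}")
    removed = int((~keep).sum())
    logger.info("detection filter removed %d of %d probes", removed, len(keep))
    return ExpressionMatrix(raw.values.loc[keep], raw.design, stage=raw.stage)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the mean of the order statistics.

    Every column ends up with the identical sorted value vector; within-column
    rank order is preserved; tied input values receive the mean of the target
    quantiles they jointly occupy (deterministic tie rule). Idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if not np.isfinite(vals).all():
        raise ValueError(
            "matrix contains missing/non-finite values; filter or impute first"
        )
    order = np.argsort(vals, axis=0, kind="stable")
    target = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col_target = np.empty(n)
        col_target[order[:, j]] = target
        # average target quantiles over tie groups
        _, inverse, counts = np.unique(vals[:, j], return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=col_target)
        out[:, j] = (sums / counts)[inverse]
    normalized = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(normalized, matrix.design, stage="normalized")


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: pd.Series, rule: str = "mean"
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene.

    Unmapped probes are dropped (with a logged count). ``rule='mean'``
    averages probes of a gene; ``rule='max_mean'`` keeps the probe with the
    highest overall mean intensity.
    """
    if len(probe_to_gene) == 0:
        raise ValueError("probe-to-gene mapping is empty")
    genes = probe_to_gene.reindex(matrix.values.index)
    mapped = genes.notna()
    dropped = int((~mapped).sum())
    if dropped:
        logger.info("collapse_probes dropped %d unmapped probes", dropped)
    sub = matrix.values.loc[mapped.to_numpy()]
    genes = genes[mapped.to_numpy()]
    if rule == "mean":
        collapsed = sub.groupby(genes.to_numpy()).mean()
    elif rule == "max_mean":
        means = sub.mean(axis=1)
        best = (
            pd.DataFrame({"gene": genes.to_numpy(), "mean": means.to_numpy()}, index=sub.index)
            .groupby("gene")["mean"]
            .idxmax()
        )
        collapsed = sub.loc[best]
        collapsed.index = best.index
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, matrix.design, stage=matrix.stage)


def baseline_log2fc(matrix: ExpressionMatrix, baseline_condition: str) -> pd.DataFrame:
    """Per-gene log2 fold change of every non-baseline condition vs baseline.

    Returns a DataFrame indexed by gene with one column per non-baseline
    condition (design order), each entry being
    ``mean(log2 values in condition) - mean(log2 values in baseline)``.
    """
    conditions = matrix.design.conditions
    if baseline_condition not in conditions:
        raise DesignError(f"unknown baseline condition: {baseline_condition!r}")
    base_mean = matrix.condition_values(baseline_condition).mean(axis=1)
    out = {}
    for cond in conditions:
        if cond == baseline_condition:
            continue
        out[cond] = matrix.condition_values(cond).mean(axis=1) - base_mean
    return pd.DataFrame(out)
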