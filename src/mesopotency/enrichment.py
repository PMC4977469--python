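"""Gene-set enrichment with the EASE score, window-based TF target
assignment, TF-regulator calling and paired gene-set t-tests.

The EASE score is a conservative variant of the one-sided Fisher exact
(hypergeometric) test: one gene is removed from the observed overlap before
computing the upper-tail probability, so a single-gene overlap can never be
significant. Enrichment fold change is (k/n) / (K/N) for an overlap k between
a query of size n and an annotation of size K over a background of size N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    """Overlap counts, EASE p-value and fold enrichment for one set."""

    set_name: str
    k: int
    n: int
    K: int
    N: int
    ease_p: float
    fold: float
    degenerate: bool = False


def ease_test(
    query: set[str], annotation: set[str], background: set[str], set_name: str = ""
) -> EnrichmentResult:
    """EASE-score enrichment of ``query`` in ``annotation`` over ``background``.

    ``ease_p`` is the hypergeometric upper-tail probability of observing at
    least ``max(k - 1, 0)`` annotated genes in the query; with k <= 1 the
    deflated overlap is 0 and the p-value is exactly 1. An empty query or
    annotation yields fold 0, p 1 and the ``degenerate`` flag.
    """
    q = set(query)
    ann = set(annotation)
    bg = set(background)
    if q - bg:
        raise ValueError(f"query members outside background: {sorted(q - bg)[:5]}")
    if ann - bg:
        raise ValueError(f"annotation members outside background: {sorted(ann - bg)[:5]}")
    n, K, N = len(q), len(ann), len(bg)
    k = len(q & ann)
    if n == 0 or K == 0:
        return EnrichmentResult(set_name, k, n, K, N, 1.0, 0.0, degenerate=True)
    deflated = max(k - 1, 0)
    # P(X >= deflated) for X ~ Hypergeom(N, K, n)
    ease_p = float(stats.hypergeom.sf(deflated - 1, N, K, n))
    fold = (k / n) / (K / N)
    return EnrichmentResult(set_name, k, n, K, N, min(ease_p, 1.0), fold)


def enrich_collection(
    query: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """EASE-test a query against every set in a collection.

    Annotation sets are intersected with the background before testing (only
    measurable genes count). Raw EASE p-values drive calling; an optional
    Benjamini-Hochberg column is appended for reference.
    """
    rows = []
    for name, members in gene_sets.items():
        res = ease_test(query, set(members) & set(background), background, set_name=name)
        rows.append(
            {
                "set": name,
                "k": res.k,
                "n": res.n,
                "K": res.K,
                "N": res.N,
                "ease_p": res.ease_p,
                "fold": res.fold,
            }
        )
    df = pd.DataFrame(rows).sort_values("ease_p", kind="stable").reset_index(drop=True)
    if bh_adjust and len(df):
        df["bh_q"] = _benjamini_hochberg(df["ease_p"].to_numpy())
    return df


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    q[order] = np.minimum.accumulate((pvals[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# TF binding-window target assignment
# ---------------------------------------------------------------------------

def assign_tf_targets(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    upstream_bp: int = 10000,
    downstream_bp: int = 3000,
) -> dict[str, set[str]]:
    """Putative TF targets from binding-peak overlap with a gene window.

    A gene is a target of a TF iff any of that TF's peaks (0-based half-open
    intervals) overlaps the strand-aware window covering the full gene body
    plus ``upstream_bp`` 5' of the TSS and ``downstream_bp`` 3' of the gene
    end. Gene models carry 0-based positions: ``tss`` is the transcription
    start base and ``gene_end`` the last transcribed base.
    """
    needed = {"gene", "chrom", "strand", "tss", "gene_end"}
    if not needed <= set(gene_models.columns):
        raise ValueError(f"gene models need columns {sorted(needed)}")
    if gene_models["strand"].isna().any() or not set(gene_models["strand"]) <= {"+", "-"}:
        raise ValueError("gene model strand must be '+' or '-'")

    windows = []
    for row in gene_models.itertuples(index=False):
        if row.strand == "+":
            start = row.tss - upstream_bp
            end = row.gene_end + 1 + downstream_bp
        else:
            start = row.gene_end - downstream_bp
            end = row.tss + 1 + upstream_bp
        windows.append((row.gene, row.chrom, start, end))

    targets: dict[str, set[str]] = {tf: set() for tf in peaks["tf"].unique()}
    by_chrom: dict[str, pd.DataFrame] = {c: g for c, g in peaks.groupby("chrom")}
    for gene, chrom, wstart, wend in windows:
        chrom_peaks = by_chrom.get(chrom)
        if chrom_peaks is None:
            continue
        hit = (chrom_peaks["start"].to_numpy() < wend) & (
            wstart < chrom_peaks["end"].to_numpy()
        )
        for tf in chrom_peaks.loc[hit, "tf"].unique():
            targets[tf].add(gene)
    return targets


def call_tf_regulators(
    results: list[EnrichmentResult] | pd.DataFrame,
    min_fold: float = 1.2,
    max_p: float = 0.05,
) -> list[str]:
    """TFs whose annotated targets are jointly enriched: fold > ``min_fold``
    AND EASE p < ``max_p``; returned sorted by ascending p-value."""
    if isinstance(results, pd.DataFrame):
        records = [
            EnrichmentResult(r["set"], r["k"], r["n"], r["K"], r["N"], r["ease_p"], r["fold"])
            for _, r in results.iterrows()
        ]
    else:
        records = list(results)
    called = [r for r in records if r.fold > min_fold and r.ease_p < max_p]
    called.sort(key=lambda r: (r.ease_p, r.set_name))
    return [r.set_name for r in called]


# ---------------------------------------------------------------------------
# paired gene-set t-test
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    t: float
    p: float
    neg_log10_p: float
    direction: int
    n_genes: int
    degenerate: bool = False


def geneset_paired_ttest(
    mean_expr_cond_a: pd.Series,
    mean_expr_cond_b: pd.Series,
    gene_set: set[str],
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired t-test of condition mean expression restricted to a gene set.

    Each gene's mean expression in condition A is paired with its own mean in
    condition B; the test runs on the per-gene differences with m - 1 degrees
    of freedom. Zero variance of the differences is degenerate (p reported as
    0 with the flag set); fewer than 3 usable genes is an error.
    """
    genes = sorted(set(gene_set) & set(mean_expr_cond_a.index) & set(mean_expr_cond_b.index))
    m = len(genes)
    if m < 3:
        raise ValueError(f"gene set has {m} usable genes; need >= 3")
    diffs = (mean_expr_cond_a.loc[genes] - mean_expr_cond_b.loc[genes]).to_numpy(dtype=float)
    mean = diffs.mean()
    direction = int(np.sign(mean))
    sd = diffs.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return PairedTestResult(0.0, 1.0, 0.0, 0, m)
        return PairedTestResult(math.inf * direction, 0.0, math.inf, direction, m, degenerate=True)
    t = mean / (sd / math.sqrt(m))
    df = m - 1
    if alternative == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(min(p, 1.0))
    neg_log10 = math.inf if p == 0 else -math.log10(p)
    return PairedTestResult(float(t), p, neg_log10, direction, m)
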