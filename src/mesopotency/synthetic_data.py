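"""Seeded synthetic-data generator with planted ground truth.

Emulates a 3-condition x 3-replicate microarray experiment over an ordered
set of culture platforms (baseline -> mid -> high, standing for the
Matrigel / replated / feeder conditions of the motivating design):

* expression: log2 intensities with planted monotone trend genes whose
  condition means are baseline + sign * effect * {0, mid_fraction, 1} plus
  i.i.d. Gaussian noise;
* methylation: 1-3 beta-value probes per gene; a configurable fraction of
  trend genes gets anti-correlated beta dynamics (expression up <=> beta
  down, the canonical promoter-methylation direction; the sign is
  configurable), clipped to [0, 1];
* annotations: gene sets with planted over-representation in the increasing
  class, plus synthetic TF binding peaks placed so that a known target list
  follows from the upstream/downstream window rule (both strands used);
* qPCR: Ct tables built by inverse construction so delta-delta-Ct recovers
  the planted fold changes, per-gene induction time-courses over
  {0, 24, 48, 72} h, and outcome proportions whose correlation with the
  primary gene's maximal induction is ~``r_true`` by construction.

Every artifact draws from its own stream seeded by ``(seed, artifact
offset)``, so artifacts are independently reproducible and the same truth
yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .containers import BetaTable, ConfigurationError, CtTable, DesignTable, ExpressionMatrix
from .induction import InductionSeries
from .io_formats import CascadeSpec

CONDITIONS = ("baseline", "mid", "high")

_STREAM_OFFSETS = {"expression": 1, "methylation": 2, "annotations": 3, "qpcr": 4}


@dataclass
class QpcrTruth:
    """Planted qPCR design: induction time-courses and outcome correlation."""

    genes: tuple[str, ...] = ("FOXQ1", "FOXC1", "FOXD1")
    reference_gene: str = "GAPDH"
    times: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    time_shape: tuple[float, ...] = (0.0, 0.4, 1.0, 0.7)  # fraction of max log2 induction
    n_units: int = 4  # cell line x protocol combinations
    n_replicates: int = 3
    base_log2_induction: float = 4.0
    unit_spread: float = 1.5
    r_true: float = 0.95
    ct_noise_sd: float = 0.0


@dataclass
class SimulationTruth:
    """Complete, seeded configuration of the planted experiment."""

    seed: int = 0
    n_genes: int = 2000
    n_conditions: int = 3
    n_replicates: int = 3
    deg_fraction_increasing: float = 0.05
    deg_fraction_decreasing: float = 0.05
    effect_size: float = 2.0
    mid_fraction: float = 0.5
    noise_sd: float = 0.5
    meth_coupled_fraction: float = 0.5
    meth_effect: float = 0.3
    meth_anticorrelated: bool = True
    beta_noise_sd: float = 0.03
    planted_set_sizes: tuple[int, ...] = (30,)
    planted_set_enrichment_fold: float = 20.0
    n_decoy_sets: int = 10
    cascade_specs: list[tuple[CascadeSpec, list[float]]] | None = None
    qpcr_truth: QpcrTruth = field(default_factory=QpcrTruth)

    def __post_init__(self) -> None:
        fracs = (self.deg_fraction_increasing, self.deg_fraction_decreasing)
        if any(not (0 <= f <= 1) for f in fracs) or sum(fracs) > 1:
            raise ConfigurationError("DEG fractions must lie in [0,1] and sum to <= 1")
        if not (0 <= self.meth_coupled_fraction <= 1):
            raise ConfigurationError("meth_coupled_fraction must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.n_conditions != 3:
            raise ConfigurationError("the planted design is 3 ordered conditions")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not (0 <= self.mid_fraction <= 1):
            raise ConfigurationError("mid_fraction must lie in [0, 1]")
        if self.planted_set_enrichment_fold < 1:
            raise ConfigurationError("planted_set_enrichment_fold must be >= 1")

    def rng(self, artifact: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM_OFFSETS[artifact]])


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _design(n_replicates: int) -> DesignTable:
    rows = [
        {"sample": f"{cond}_{r}", "condition": cond, "replicate": r}
        for cond in CONDITIONS
        for r in range(1, n_replicates + 1)
    ]
    return DesignTable(pd.DataFrame(rows))


def plant_labels(truth: SimulationTruth) -> pd.Series:
    """Planted class per gene: 'increasing', 'decreasing' or 'null'."""
    genes = _gene_names(truth.n_genes)
    n_inc = round(truth.deg_fraction_increasing * truth.n_genes)
    n_dec = round(truth.deg_fraction_decreasing * truth.n_genes)
    labels = ["increasing"] * n_inc + ["decreasing"] * n_dec
    labels += ["null"] * (truth.n_genes - len(labels))
    return pd.Series(labels, index=genes, name="class")


def simulate_expression(truth: SimulationTruth) -> tuple[ExpressionMatrix, pd.Series]:
    """Log2 expression matrix plus the planted per-gene class labels."""
    rng = truth.rng("expression")
    labels = plant_labels(truth)
    design = _design(truth.n_replicates)
    baselines = rng.uniform(6.0, 12.0, size=truth.n_genes)
    sign = np.where(labels == "increasing", 1.0, np.where(labels == "decreasing", -1.0, 0.0))
    fractions = np.array([0.0, truth.mid_fraction, 1.0])
    means = baselines[:, None] + sign[:, None] * truth.effect_size * fractions[None, :]
    values = np.repeat(means, truth.n_replicates, axis=1)
    values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)
    df = pd.DataFrame(values, index=labels.index, columns=design.samples)
    return ExpressionMatrix(df, design), labels


def simulate_methylation(
    truth: SimulationTruth, gene_labels: pd.Series
) -> tuple[BetaTable, pd.Series]:
    """Beta-value table (1-3 probes/gene) plus per-gene coupling labels.

    For the coupled fraction of trend genes the beta condition means move
    against (or, if configured, with) the expression trend by
    ``meth_effect`` at the high condition; other genes are flat up to noise.
    """
    rng = truth.rng("methylation")
    genes = list(gene_labels.index)
    design = _design(truth.n_replicates)
    n_probes = rng.integers(1, 4, size=len(genes))

    trend_genes = [g for g in genes if gene_labels[g] != "null"]
    n_coupled = round(truth.meth_coupled_fraction * len(trend_genes))
    coupled = set(
        rng.choice(trend_genes, size=n_coupled, replace=False) if n_coupled else []
    )
    meth_labels = pd.Series(
        ["coupled" if g in coupled else "uncoupled" for g in genes],
        index=genes,
        name="meth_class",
    )

    meth_sign = -1.0 if truth.meth_anticorrelated else 1.0
    fractions = np.array([0.0, truth.mid_fraction, 1.0])
    probe_ids, probe_genes, rows = [], [], []
    for gene, count in zip(genes, n_probes):
        expr_sign = {"increasing": 1.0, "decreasing": -1.0, "null": 0.0}[gene_labels[gene]]
        shift = meth_sign * expr_sign * truth.meth_effect if gene in coupled else 0.0
        for j in range(1, count + 1):
            base = rng.uniform(0.35, 0.65)
            means = base + shift * fractions
            vals = np.repeat(means, truth.n_replicates)
            vals = vals + rng.normal(0.0, truth.beta_noise_sd, size=vals.shape)
            rows.append(np.clip(vals, 0.0, 1.0))
            probe_ids.append(f"{gene}_p{j}")
            probe_genes.append(gene)
    betas = pd.DataFrame(np.array(rows), index=probe_ids, columns=design.samples)
    pmap = pd.Series(probe_genes, index=probe_ids, name="gene")
    return BetaTable(betas, pmap, design), meth_labels


@dataclass
class AnnotationTruth:
    """Planted annotation artifacts and their ground truth."""

    gene_sets: dict[str, set[str]]
    planted_sets: list[str]
    peaks: pd.DataFrame
    gene_models: pd.DataFrame
    tf_targets: dict[str, set[str]]


def simulate_annotations(truth: SimulationTruth, gene_labels: pd.Series) -> AnnotationTruth:
    """Gene sets enriched in the increasing class, plus TF peaks/gene models.

    The planted TF ('FOXC1') binds 5 kb upstream of 80% of increasing-class
    genes and 5% of the rest; a decoy TF binds a random 10%. Gene bodies are
    10 kb, anchored 1 Mb apart on one chromosome with alternating strands, so
    the 10 kb / 3 kb window rule recovers exactly the planted target lists.
    """
    rng = truth.rng("annotations")
    genes = list(gene_labels.index)
    n = len(genes)
    increasing = [g for g in genes if gene_labels[g] == "increasing"]
    others = [g for g in genes if gene_labels[g] != "increasing"]

    gene_sets: dict[str, set[str]] = {}
    planted_names = []
    k_inc = max(len(increasing), 1)
    for i, size in enumerate(truth.planted_set_sizes, start=1):
        # overlap implied by the requested fold: (k/size) / (K_inc/N) = fold
        k = min(size, len(increasing), round(size * truth.planted_set_enrichment_fold * k_inc / n))
        members = set(rng.choice(increasing, size=k, replace=False)) if k else set()
        if size - k > 0:
            members |= set(rng.choice(others, size=size - k, replace=False))
        name = f"planted_set_{i}"
        gene_sets[name] = members
        planted_names.append(name)
    for i in range(1, truth.n_decoy_sets + 1):
        size = min(30, n)
        gene_sets[f"decoy_set_{i}"] = set(rng.choice(genes, size=size, replace=False))

    anchors = 1_000_000 * (np.arange(n) + 1)
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    gene_len = 10_000
    models = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chr1",
            "strand": strands,
            "tss": np.where(strands == "+", anchors, anchors + gene_len - 1),
            "gene_end": np.where(strands == "+", anchors + gene_len - 1, anchors),
        }
    )

    planted_targets = set(increasing[: round(0.8 * len(increasing))])
    n_bg_targets = round(0.05 * len(others))
    if n_bg_targets:
        planted_targets |= set(rng.choice(others, size=n_bg_targets, replace=False))
    decoy_targets = set(rng.choice(genes, size=round(0.1 * n), replace=False)) if n else set()

    peak_rows = []
    tss_by_gene = dict(zip(models["gene"], models["tss"]))
    strand_by_gene = dict(zip(models["gene"], models["strand"]))
    for tf, target_set in (("FOXC1", planted_targets), ("DECOY_TF", decoy_targets)):
        for gene in sorted(target_set):
            tss = tss_by_gene[gene]
            if strand_by_gene[gene] == "+":
                start, end = tss - 5000, tss - 4800
            else:
                start, end = tss + 4801, tss + 5001
            peak_rows.append(("chr1", int(start), int(end), tf))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "tf"])
    return AnnotationTruth(
        gene_sets, planted_names, peaks, models, {"FOXC1": planted_targets, "DECOY_TF": decoy_targets}
    )


@dataclass
class QpcrData:
    """Synthetic Ct table with its planted induction/outcome truth."""

    ct_table: CtTable
    series: list[InductionSeries]  # one per (gene, unit), gene named "GENE@unit"
    max_inductions: pd.DataFrame  # gene x unit, linear folds
    outcomes: pd.Series  # per unit, proportion in [0, 1]


def simulate_qpcr(truth: SimulationTruth) -> QpcrData:
    """Ct time-course table, induction truth, and correlated outcomes.

    Ct values are built by inverse construction: the reference gene sits at a
    constant Ct and each gene's Ct encodes its planted dCt trajectory, so
    with zero Ct noise the delta-delta-Ct chain recovers the planted fold
    changes exactly. Outcome proportions are an affine rescaling of
    ``r_true * x_std + sqrt(1 - r_true^2) * noise`` against the primary
    gene's maximal linear induction, which preserves the planted correlation.
    """
    q = truth.qpcr_truth
    if not (-1 < q.r_true <= 1):
        raise ConfigurationError("r_true must lie in (-1, 1]")
    rng = truth.rng("qpcr")
    units = [f"unit{i}" for i in range(1, q.n_units + 1)]
    shape = np.asarray(q.time_shape, dtype=float)

    # planted per-unit max log2 induction of the primary gene, shared trend
    unit_scores = rng.normal(0.0, 1.0, size=q.n_units)
    max_log2 = {}
    for gi, gene in enumerate(q.genes):
        base = q.base_log2_induction + 0.5 * gi
        max_log2[gene] = base + q.unit_spread * unit_scores

    # Ct table: wells grouped by (unit, time)
    base_dct = {gene: rng.uniform(-6.0, -2.0) for gene in q.genes}
    ref_ct = 20.0
    design_rows, columns, ct_rows_by_gene = [], [], {g: [] for g in (*q.genes, q.reference_gene)}
    for unit in units:
        for t_idx, t in enumerate(q.times):
            group = f"{unit}:t{int(t)}"
            for rep in range(1, q.n_replicates + 1):
                sample = f"{group}_r{rep}"
                columns.append(sample)
                design_rows.append({"sample": sample, "condition": group, "replicate": rep})
                for gene in q.genes:
                    log2_fold = max_log2[gene][units.index(unit)] * shape[t_idx]
                    dct = base_dct[gene] + log2_fold
                    noise = rng.normal(0.0, q.ct_noise_sd) if q.ct_noise_sd > 0 else 0.0
                    ct_rows_by_gene[gene].append(ref_ct - dct + noise)
                ct_rows_by_gene[q.reference_gene].append(ref_ct)
    values = pd.DataFrame(
        {c: [ct_rows_by_gene[g][i] for g in (*q.genes, q.reference_gene)] for i, c in enumerate(columns)},
        index=[*q.genes, q.reference_gene],
    )
    design = DesignTable(pd.DataFrame(design_rows))
    ct_table = CtTable(values, q.reference_gene, design)

    series = []
    max_ind = {}
    for gene in q.genes:
        folds_by_unit = []
        for ui, unit in enumerate(units):
            folds = list(2.0 ** (max_log2[gene][ui] * shape))
            series.append(InductionSeries(f"{gene}@{unit}", list(q.times), folds))
            folds_by_unit.append(max(folds))
        max_ind[gene] = folds_by_unit
    max_df = pd.DataFrame(max_ind, index=units).T

    x = max_df.loc[q.genes[0]].to_numpy(dtype=float)
    x_std = (x - x.mean()) / x.std()
    noise = rng.normal(0.0, 1.0, size=q.n_units)
    y_raw = q.r_true * x_std + math.sqrt(max(1.0 - q.r_true**2, 0.0)) * noise
    lo, hi = y_raw.min(), y_raw.max()
    scaled = (y_raw - lo) / (hi - lo) if hi > lo else np.full_like(y_raw, 0.5)
    outcomes = pd.Series(0.05 + 0.9 * scaled, index=units, name="outcome")
    return QpcrData(ct_table, series, max_df, outcomes)


DEFAULT_CASCADES: list[tuple[CascadeSpec, list[float]]] = [
    (
        CascadeSpec("activator_chain", ["CA1", "CA2", "CA3"], [+1, +1], "Induction"),
        [1.5, 0.8, 2.0],
    ),
    (
        CascadeSpec("mixed_chain", ["CB1", "CB2", "CB3", "CB4"], [-1, +1, -1], "Induction"),
        [-2.0, 0.5, -0.5, 1.0],
    ),
]


def simulate_all(truth: SimulationTruth):
    """Generate every artifact; returns a dict keyed by artifact name."""
    expr, labels = simulate_expression(truth)
    betas, meth_labels = simulate_methylation(truth, labels)
    annotations = simulate_annotations(truth, labels)
    qpcr = simulate_qpcr(truth)
    cascades = truth.cascade_specs if truth.cascade_specs is not None else DEFAULT_CASCADES
    return {
        "expression": expr,
        "labels": labels,
        "methylation": betas,
        "meth_labels": meth_labels,
        "annotations": annotations,
        "qpcr": qpcr,
        "cascades": cascades,
    }


def write_simulation(truth: SimulationTruth, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact to ``outdir`` as plain-text files.

    Returns the path of each written artifact. Deterministic: the same truth
    produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_all(truth)
    paths: dict[str, Path] = {}

    expr: ExpressionMatrix = data["expression"]
    paths["expression"] = outdir / "expression.tsv"
    io_formats.write_expression_table(expr, paths["expression"])
    paths["design"] = outdir / "design.tsv"
    io_formats.write_design_table(expr.design, paths["design"])
    paths["labels"] = outdir / "truth_labels.tsv"
    data["labels"].rename_axis("gene").to_frame().assign(
        meth_class=data["meth_labels"]
    ).to_csv(paths["labels"], sep="\t")

    betas: BetaTable = data["methylation"]
    paths["methylation"] = outdir / "methylation.tsv"
    io_formats.write_beta_table(betas, paths["methylation"])
    paths["probe_map"] = outdir / "probe_map.tsv"
    io_formats.write_probe_map(betas.probe_to_gene, paths["probe_map"])

    ann: AnnotationTruth = data["annotations"]
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    io_formats.write_gene_sets(ann.gene_sets, paths["gene_sets"])
    paths["peaks"] = outdir / "peaks.bed"
    io_formats.write_bed_peaks(ann.peaks, paths["peaks"])
    paths["gene_models"] = outdir / "gene_models.tsv"
    io_formats.write_gene_models(ann.gene_models, paths["gene_models"])

    qpcr: QpcrData = data["qpcr"]
    paths["ct_table"] = outdir / "ct_table.tsv"
    io_formats.write_ct_table(qpcr.ct_table, paths["ct_table"])
    paths["ct_design"] = outdir / "ct_design.tsv"
    io_formats.write_design_table(qpcr.ct_table.design, paths["ct_design"])
    paths["outcomes"] = outdir / "outcomes.tsv"
    qpcr.outcomes.rename_axis("unit").to_csv(paths["outcomes"], sep="\t")

    paths["cascades"] = outdir / "cascades.txt"
    io_formats.write_cascades([spec for spec, _ in data["cascades"]], paths["cascades"])
    fc_rows = {}
    for spec, fcs in data["cascades"]:
        fc_rows.update(dict(zip(spec.components, fcs)))
    paths["cascade_fc"] = outdir / "cascade_log2fc.tsv"
    pd.Series(fc_rows, name="log2fc").rename_axis("gene").to_csv(paths["cascade_fc"], sep="\t")
    return paths
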