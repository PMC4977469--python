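# Methods

`mesopotency` re-implements, as a tested library, the computational chain
used to compare human embryonic stem-cell (hESC) culture platforms by their
mesoderm/cardiomyogenesis propensity. The experimental design it models is
three ordered culture conditions — generically `baseline` → `mid` → `high`,
standing for Matrigel (MGEL), Matrigel-replated-on-feeders (RPL), and mouse
embryonic fibroblast feeders (MEF) — with three biological replicates each,
profiled by expression microarray, methylation array (beta values), and
qPCR time-courses during directed differentiation.

## Preprocessing

Arrays are handled on the log2 scale. Detection filtering keeps a probe if
its detection p-value passes the threshold (default 0.05) in at least one
sample; a strict all-samples mode is provided because array studies differ
on this point and the permissive rule matches common Illumina practice.
Quantile normalization maps every column onto the mean of the per-column
order statistics; tied input values receive the mean of the target
quantiles they jointly occupy, which makes the operation deterministic and
idempotent. Multi-probe genes collapse by the probe mean (a max-mean-probe
rule is available). Fold changes are differences of per-condition means
against the named baseline condition, so the baseline's own log2FC is 0 by
construction.

## Rank-product differential calling

For conditions A (n_a replicates) and B (n_b), every one of the
K = n_a·n_b cross-condition replicate pairings yields per-gene log2 fold
changes. Genes are ranked within each pairing (rank 1 = most extreme in the
tested direction; ties take average ranks) and summarized by the rank
product RP_g = (∏_k rank_{g,k})^{1/K}. Up- and down-regulation are tested
separately; exchanging the conditions exchanges the directions exactly.

Error control is permutation-based. For each gene, E(g) is the expected
number of null genes with RP ≤ RP_g under a permutation null; the per-gene
null probability is p(g) = E(g)/G, and the proportion of false positives is
PFP(g) = E(g)/rank(g), forced monotone down the RP-ranked list by a
cumulative maximum (so calls form a contiguous prefix) and clipped to
[0, 1]. Significance is PFP ≤ the configured FDR (default 5%).

Two permutation nulls are exposed, because the choice matters and no single
scheme dominates:

* `column` (default): within-condition residuals (values minus the gene's
  condition mean, rescaled by √(n/(n−1)) to restore the variance lost to
  centering) are scrambled independently within each sample column; pairing
  fold changes and ranks are then recomputed. Pairings sharing a replicate
  remain correlated under this null, matching the observed rank structure,
  so the per-gene type-I error is calibrated at its nominal level. The cost
  is conservatism when a large fraction of genes carries strong signal:
  those genes displace nulls down the observed ranking, a displacement no
  all-null ensemble reference can represent, and realized recall drops well
  below what the RP statistic itself could deliver at a fixed false-
  discovery proportion.
* `independent`: the classical rank-product assumption — within-pairing
  ranks permute independently, making the null exactly enumerable (a null
  gene's rank vector is uniform on {1..G}^K). It is the more powerful
  scheme but anti-conservative on replicated designs, because real pairings
  sharing a replicate are correlated (ρ = 0.5 for i.i.d. noise) and the
  independent null under-weights the heavy lower tail of RP.

The same machinery runs on methylation beta values per probe, with an
additional gate |Δβ| ≥ 0.25 between the compared conditions; a gene is
differentially methylated if any of its probes passes both gates, and the
full per-gene list of probe Δβ values is retained for the consistency
check.

## Regulation dynamics

A gene's dynamics are described by (fc_mid, fc_high), its log2FC against
baseline in the two non-baseline conditions. The mid → high transition is
*increased* when both values share a sign and the later value is farther
from zero, *decreased* when closer to zero, *reversed* when the sign flips,
*unchanged* otherwise; a value within ±tol of zero inherits the other
value's sign (default tol = 0; the parameter exists because exact-zero
comparisons are brittle on arrays). A separate monotone-trend call
(0 ≤ fc_mid ≤ fc_high with fc_high > tol, and its mirror) picks out genes
tracking the differentiation-efficiency ranking of the platforms.

Fold-change profiles are clustered by Lloyd-style k-means with dot-product
similarity on un-normalized profiles (K = 3 by default, matching the three
dynamic classes; cosine similarity is an option). Because the mean-centroid
update does not guarantee a non-decreasing dot-product objective, iteration
additionally stops — keeping the previous state — if the objective would
decrease; the reported objective trace is therefore provably monotone.
Empty clusters are re-seeded from the point most dissimilar to its
centroid; everything is deterministic under the seed.

Methylation probes with |Δβ| > 0.15 must agree in direction for a gene to
be called consistent; genes on a configurable exclusion list (the GNAS
complex locus by default, a known imprinted region whose probes disagree)
are consistent by fiat, as are genes with at most one qualifying probe.
Association between an expression class and a methylation class is a
two-sided Fisher exact test on the 2×2 co-membership table over the genes
measured on both platforms.

## Enrichment

The EASE score deflates the observed overlap by one gene before taking the
hypergeometric upper tail, so a single-gene overlap can never be
significant; the p-value is therefore always ≥ the classical one-sided
Fisher p on the same table. Fold enrichment is (k/n)/(K/N). Raw EASE
p-values drive calling (a Benjamini–Hochberg column is reported for
reference); TF regulators are called at fold > 1.2 and p < 0.05.

TF targets are assigned by a strand-aware window: the full gene body plus
10 kb 5′ of the TSS and 3 kb 3′ of the gene end, with 0-based half-open
interval overlap against BED peaks. Gene-set condition differences use a
classical paired t-test on per-gene differences of condition means
(two-sided by default; m − 1 degrees of freedom; at least 3 usable genes).

## Signaling-cascade propensity

Each component of an ordered signed cascade is scored as
(outgoing edge sign) × (its own log2FC): a down-regulated inhibitor
(log2FC = −2 on a `-|` edge) contributes +2. The final gene component,
feeding a non-gene terminal label such as "Mesoderm Induction", is scored
with sign +1 — this convention reproduces the published per-cascade means,
which list one scored value per gene component; `include_terminal=False`
scores only components with an explicit downstream gene, matching the
narrower worked example. Cascades are ranked by mean propensity
(half-away-from-zero 2-decimal rounding for reporting; ties broken by
name) and flagged consistent when every component propensity is positive.

## qPCR induction

ΔCt = mean Ct(reference) − mean Ct(gene) within a sample group is the log2
expression relative to the housekeeping reference (GAPDH in the motivating
data); ΔΔCt differences between groups are log2 fold changes, 2^ΔΔCt the
linear fold. Induction is the fold change versus the gene's own time-0
group; the maximal induction within the first 72 h is the early predictor.
Its association with the final differentiation outcome uses Pearson r with
t = r√(n−2)/√(1−r²) and a one-tailed upper p (positive association is the
hypothesis; a two-sided mode exists). Undetermined wells are excluded,
never imputed at max cycles, since imputation would bias ΔΔCt.

## Synthetic data

The generator plants ground truth for every stage at the study's design
(defaults: 2000 genes, 3 conditions × 3 replicates):

* expression: 5% + 5% of genes increase/decrease monotonically with
  condition means baseline + sign · effect · {0, ½, 1} (effect 2.0 log2FC,
  half realized in the mid condition) plus i.i.d. Gaussian noise
  (sd 0.5 log2 units — a typical between-replicate array spread; no noise
  level is dictated by the design being emulated);
* methylation: 1–3 probes per gene; half of the trend genes get
  anti-correlated beta dynamics of magnitude 0.3 (clipped to [0, 1], beta
  noise sd 0.03) — expression up ⇔ beta down, the canonical
  promoter-methylation direction, with the sign configurable;
* annotations: one 30-gene set drawn (at the requested enrichment fold)
  from the increasing class plus random decoy sets; a planted TF binding
  5 kb upstream of 80% of increasing genes and 5% of the rest, on genes
  laid out 1 Mb apart with alternating strands so the window rule recovers
  the target list exactly;
* qPCR: Ct tables built by inverse construction (reference at constant Ct)
  so the ΔΔCt chain recovers the planted time-courses exactly at zero Ct
  noise; outcome proportions are an affine rescaling of
  r·x_std + √(1−r²)·ε against the primary gene's maximal induction, which
  preserves the planted correlation (r = 0.95 by default, n = 4 units).

Each artifact draws from its own stream seeded by (seed, artifact offset),
so identical truth gives byte-identical files. The generator emulates
planted monotone effects and independent Gaussian noise only — no batch,
spatial, or probe-affinity artifacts, no heavy-tailed outliers, no
between-gene correlation — so passing recovery tests demonstrates the
machinery's correctness on its stated model, not robustness to real-array
pathology.

## Numerical choices and limitations

* Probabilities from scipy (hypergeometric, Fisher, Student t); test-suite
  oracles recompute them by exact rational enumeration or analytic CDFs.
* Rank-product equality between floating-point geometric-mean ranks is
  guarded by a 1e-9 relative tolerance when counting null values, so tied
  integer rank products are not split by last-ulp jitter.
* `fdr = 0` is treated as the degenerate boundary (no calls) rather than an
  error; at permissive thresholds (≥ 0.5) a gene passing in both directions
  is assigned to the direction with the smaller RP.
* The PFP estimator measures false positives against an all-null ensemble
  of G genes. When a large fraction of genes carries strong signal, that
  reference cannot represent the displacement of nulls down the observed
  ranking: the calibrated null then under-calls (lower recall at a fixed
  PFP threshold) while the independent null over-calls. Both behaviors are
  inherent to the method's definition, not to this implementation; choose
  the scheme by whether type-I control or power matters more.
* Simulation scale in the test suite: statistical checks run at 2000 genes,
  3v3, 100 permutations and up to 50 seeds; fast structural checks use
  300–500 genes.
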