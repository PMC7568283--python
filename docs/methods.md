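# Methods

This note documents the models, statistics and design choices behind the
pipeline, what the synthetic-cohort generator does and does not emulate,
and the numerical conventions the implementation commits to.

## Quality control

Per nucleus we compute the number of detected genes (counts > 0), the UMI
total, and the mitochondrial UMI fraction. A nucleus is removed when it has
≤ 200 detected genes, ≥ 20,000 UMIs, or ≥ 20% mitochondrial UMIs; the
boundary value itself is always removed, so the kept set satisfies the
strict inequalities. Filtering is therefore idempotent. Mitochondrial
genes are recognized by the "MT-" symbol prefix by default; an explicit
predicate can be supplied. The mitochondrial criterion is interpreted as a
fraction of UMIs (the standard convention); a fraction-of-genes reading is
not implemented. The pipeline assumes its inputs already contain called
cells — no barcode-calling (knee-point) step is reproduced.

The per-sample QC summary reports mean genes and UMIs per kept nucleus,
and `pmd_independence` checks that these means are uncorrelated with
postmortem delay (Pearson r, two-sided t test on n − 2 df; constant inputs
are flagged degenerate with r reported as 0).

## Normalization, HVGs, embedding, clustering

Expression is log-normalized per cell: x = ln(1 + c·10⁴/total); all-zero
cells map to all-zero columns. Highly variable genes are ranked by the
variance-stabilizing criterion: a lowess trend (span 0.3) of log₁₀
variance against log₁₀ mean is fitted over raw counts, each gene is
standardized by its fitted standard deviation with standardized values
clipped at √n_cells, and genes are ranked by the variance of the clipped
values, ties broken by gene id. PCA runs on the HVG submatrix after
per-gene scaling to zero mean / unit variance with values clipped at ±10;
a full SVD is used and each component's sign is fixed so its
largest-magnitude loading is positive, making embeddings reproducible.

Clustering builds a k-nearest-neighbor graph (k = 20, Euclidean, on the
first 20 PCs), converts it to a shared-nearest-neighbor graph with Jaccard
weights over neighbor sets (self included) pruned below 1/15, and runs
Leiden modularity optimization (RB configuration, resolution 1 for the
type-level pass) to convergence with a fixed seed. Labels are renumbered
by decreasing size. Two deliberate deviations from the reference
toolchain: (1) multi-sample integration by anchor finding is not
reproduced — per-gene scaling is computed on the pooled cohort (the
synthetic cohorts have no batch structure; for real data a per-sample
centering mode would be the first mitigation to add); (2) the community
detection algorithm is Leiden rather than SLM, so partitions are not
expected to be label-identical to any particular run of other tools —
recovery of planted structure, not label equality, is the tested contract.
At resolution 1 a large, internally homogeneous type can legitimately
split into several clusters; the annotation step collapses such splits, so
type-recovery is evaluated on annotated types.

Marker discovery is one-vs-rest per cluster: genes pre-filtered at
|log₂FC| ≥ 0.25, Wilcoxon-tested, adjusted within the tested gene set of
the cluster, significant at adjusted P < 0.1. Cluster annotation scores
each reference cell type as the mean over its marker genes of the gene's
z-score (across cluster mean-expression profiles); the best-scoring type
must beat the runner-up by a margin (default 0, i.e. any strict win) or
the cluster is "unassigned".

## Differential expression

The test of record is the two-sample Wilcoxon rank-sum test on
log-normalized expression with cells as the units — matching the standard
single-cell toolchain, and inheriting its known caveat that cells from the
same subject are not independent (a per-sample pseudobulk analysis is the
orthodox remedy; it is out of scope here because the tested contract is
the cell-level procedure). Modes:

- **exact**: the tie-free rank-sum null is enumerated by dynamic
  programming (counts of size-n₁ subsets of {1..N} per rank-sum);
  two-sided p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1.
- **normal**: mean n₁n₂/2, variance n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))]
  with the standard tie correction, continuity correction of ½, two-sided.
- **auto** uses exact when n₁+n₂ ≤ 16 and the pooled sample is tie-free.

When every value is identical across both groups the test is flagged
degenerate with p = 1. The genome-wide scan path vectorizes the normal
approximation over genes (row-wise ranks with per-gene tie terms).

Fold changes are computed on de-logged means: log₂[(mean(eˣ−1)+ε) /
(mean(eˣ−1)+ε)] with ε = 10⁻⁹, so thresholds stated in log₂ units apply
directly; swapping the groups exactly negates the value. Adjustment is
Bonferroni by default — mirroring the reference toolchain's default, since
only "adjusted P" is specified by the procedure this follows — with
Benjamini–Hochberg step-up selectable; both are applied within the tested
gene set of each cell type. Genes with zero expression in every cell of a
type are untestable and omitted from that type's records. DEGs require
adjusted P < 0.1 and |log₂FC| ≥ 0.1. Cross-type overlap reports per-type
up/down counts, genes significant in all types, and genes exclusive to
one type.

## Subpopulation enrichment and proportion shifts

Each configured cell type (glial and vascular types; neurons excluded by
default) is re-clustered with the same HVG → scale → PCA → SNN → Leiden
stack at its type resolution (astrocyte 0.2, endothelial 0.2, microglia
0.3, oligodendrocyte 0.2), with a 50-cell floor below which a single
subpopulation is returned.

The enrichment score z-scores each DEG's normalized expression across
*all* cells of the type (zero-variance genes contribute 0) and averages
over the subpopulation's cells and the DEG set's genes; up- and
down-regulated DEG sets are scored separately. Scoring per cell before
averaging (rather than z-scoring subpopulation means) makes the score
robust to subpopulation sizes and yields the centering identity — the
cell-count-weighted mean of any score over a type's subpopulations is
exactly 0 — which the test suite asserts to 10⁻⁹ on every cohort. A
subpopulation is classified up-regulated (down-regulated) when the
corresponding score exceeds 0.5; if both exceed it, the larger wins and an
exact tie is "ambiguous". The threshold applies per direction, consistent
with reporting separate "up-regulated" and "down-regulated"
subpopulations. Classification is monotone in the threshold.

Subpopulation signatures compare pooled up-regulated vs pooled
down-regulated cells with the same DE machinery; if either side is empty
the comparison is undefined and raises.

Proportion shifts use samples as the unit: per-sample within-type shares,
condition means and SEM (sd/√n, ddof = 1), the percentage-point delta
(mean_case − mean_control, ×100) and the relative delta
((mean_case − mean_control)/mean_control). Both delta conventions are
always emitted because "X% larger" phrasing is ambiguous between them.
Samples contributing no cells of the type are excluded from that type's
means with a warning.

## Cross-study concordance

Internal significant DEGs are inner-joined to an external DE table on
uppercased, whitespace-stripped gene symbols (duplicate external rows
collapse to the median effect, flagged). Replicable DEGs are the matched
genes with external adjusted P strictly below α = 0.05. Direction
concordance is the percentage of replicable genes whose effect signs
agree, excluding zero-effect rows (their count is reported); a per-type
breakdown and its mean accompany the pooled percentage, since pooled and
per-type-averaged values can differ.

## Synthetic cohort generator

The generator emulates a 21-subject cohort design (12 case, 9 control) at
desk scale. Gene baseline means are lognormal (median 0.25 counts/cell,
σ = 1), giving realistic snRNA-seq sparsity at a 2,000-gene panel; counts
are negative binomial with mean = lib_factor × base_mean × 2^(sum of
applicable log₂ effects) and a single shared dispersion (size = 1/φ,
φ = 1 by default). Effects multiply the mean: cell-type markers (10 genes
at log₂FC 3 by default, the first carrying the canonical symbol of its
type so reference annotation works end-to-end), subpopulation markers (12
genes at 2.5 — the regime where subpopulations are genuinely separable by
subclustering), case-condition DEGs (scoped to a type, optionally to one
subpopulation), and constitutive signature enrichment
(`deg_overexpression_log2fc`): a disease-associated subpopulation shifts
its type's up-DEGs by +x and down-DEGs by −x in both conditions (default
±2 in the default config).

Planted DEG and marker genes are floored at expressed baseline levels
(the cohort median; half-median for markers' floor rationale is the same):
a z-score signature is physically bounded by detection — on genes detected
in ~10% of cells even an 8-fold shift cannot push the mean z past ~0.5 —
so planted "associated" subpopulations must be expressed and strongly
shifted to actually be associated under the 0.5 criterion. This is a
property of the statistic, not of the implementation.

Cells are apportioned to samples, types, subpopulations and debris by
largest-remainder rounding, so planted proportions hold exactly and all
randomness lives in expression sampling. Library size is a per-cell
lognormal factor (σ = 0.35, median 1). Systematic per-sample depth
offsets are deliberately not modeled: they would make any cell-level test
anti-conservative under the null (a real phenomenon the cell-as-unit
design cannot absorb), and the generator's contract is exchangeability of
case and control cells when no effect is planted. Debris nuclei (5% per
sample) have library sizes scaled by 0.1, putting them under the 200-gene
floor; a configurable share (30%) instead keeps normal depth but carries
an expected ~50% mitochondrial share, well past the 20% boundary despite
negative-binomial noise. Not emulated: gene–gene correlation beyond the
planted block structure, ambient RNA, doublets, batch effects, and
per-sample depth offsets — so passing tests demonstrate correctness of
the procedures under the stated generative model, not robustness to those
real-data phenomena.

Ground truth records every cell's sample, condition, type, subpopulation
and debris status, every gene's planted roles, and the planted share per
subpopulation and condition. Everything is bit-reproducible for a fixed
seed.

## Problem sizes and numerical conventions

The validation suite runs at desk scale, chosen so each check is decisive
under the generative model: type-I error on 2 × 2,000-cell groups over
2,000 genes; DEG recovery with 50 planted genes at |log₂FC| = 1 over
5 + 5 samples × 500 cells; clustering recovery on 6 + 6 × 300 cells;
enrichment recovery over 10 seeds of a 3,600-cell astrocyte compartment;
proportion-shift recovery of a planted 20-pp change over 6 + 6 × 400
cells. The acceptance script runs the full default cohort
(21 × 400 cells, 2,000 genes) plus an independent replication cohort.

Ties break lexicographically (gene ids, cluster ids) everywhere a rank is
ambiguous. Exact p-values are deterministic; the normal approximation
agrees with the exact enumeration within 0.02 for 8 + 8 tie-free samples
(asserted exhaustively). Adjusted p-values preserve input order.
Numeric CSV output uses repr-faithful precision (%.17g) so on-disk
round-trips are exact to the last bit that matters at 12 significant
digits.
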