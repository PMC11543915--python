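# Methods

This note documents the statistical procedures implemented in
`blastcomp`, the synthetic data model used to validate them, the
numerical choices made where the design was genuinely open, and the
limits of what the test suite demonstrates.

## The comparison problem

Blastoid models are profiled by different labs on different platforms:
droplet UMI counts (10x-style) and plate-based TPM (SMART-seq-style).
Direct expression comparison across such datasets is confounded by
depth, chemistry and batch. The pipeline therefore compares datasets
through *derived, comparison-robust summaries*: cell-type composition
vectors, cluster-occupancy distributions, per-dataset-standardized
module-score distributions, and rank-based pathway activities. Each
summary has its own invariances (per-dataset z-scaling removes
location/scale; AUC activity is invariant to any monotone transform of
a cell's expression; KS distances depend only on distribution shape),
which is what makes cross-platform comparison defensible.

## Synthetic cohort model

The generator emulates the statistical structure the analysis assumes,
not the full biology:

- **Gene universe.** `n_genes` (default 2000) with log-normal baseline
  means (meanlog 0, sdlog 1) shared across datasets. The bundled
  lineage marker symbols (EPI_ICM 6, PE 4, TE 3, AMN 7, EVT 9, STB 12)
  are planted as named genes; EVT/STB are named but not inflated.
- **Programs.** A lineage program multiplies its markers' means by
  `exp(marker_log_fold_change)` (default 2.0 on the natural-log scale)
  and renormalizes to a probability vector over genes. Cell types:
  EPI_ICM, PE_I (PE program), PE_II (PE + AMN programs — the
  amnion-biased endoderm subtype), TE, and `intermediate_EPI_TE`
  cells whose expected relative expression is exactly
  `w·p(EPI_ICM) + (1−w)·p(TE)` with `w ~ U(0,1)` recorded per cell.
  Mixing the *normalized* programs keeps this mixture property exact,
  which the tests assert against the analytic mean.
- **Composition archetypes.** `balanced` (34/27/4/35% over
  EPI/PE_I/PE_II/TE before the intermediate fraction),
  `epi_enriched` (62/12/4/22) and `pe_enriched` (16/34/28/22), each
  diluted by the intermediate fraction (default 10%). These mirror the
  three observed blastoid composition regimes: blastocyst-like
  balance, nPSC-style EPI enrichment, and EPSC/fibroblast-style PE
  enrichment with a large PE-II/ambiguous load.
- **Counts.** UMI: negative binomial with gene-level dispersion 0.3
  (variance μ + 0.3μ²) around per-cell log-normal depths (mean 5000,
  sdlog 0.3). TPM: per-entry log-normal noise (sdlog 0.5) on the
  program, rescaled so every cell sums to 1e6. Optional Bernoulli
  dropout (default 0 — the NB is already zero-rich).
- **Mitochondrial fraction.** A Beta draw per cell (mean 0.08,
  concentration 15 — roughly 4% of cells above the 20% QC cutoff, so
  the filter path is exercised) recorded as metadata; an option
  additionally materializes an `MT-` gene block whose count share
  matches the draw.
- **Batch effect.** Per-dataset multiplicative log-normal shift on
  gene means (sdlog 0.1).
- **Seeding.** The cohort seed drives a cohort-level stream (shared
  gene means); dataset *i* uses an offset stream (`seed + i + 1`)
  whose first draw is the batch shift, so identical spec + seed is
  byte-identical and per-dataset generation is independent.

Not emulated: ambient RNA, doublets, gene–gene correlation beyond the
lineage programs, UMI saturation, and real marker dropout patterns.
Passing tests therefore demonstrate correctness of the *statistics*
under a known generative model, not robustness to every artifact of
real data.

## QC

Order: genes detected in `< 10` cells are removed first; then cells
with `< 100` detected genes, cells with mitochondrial fraction
strictly `> 0.20`, and — for UMI data only — cells outside
density-inflection bounds on total counts (TPM cells all sum to ~1e6,
so the counts rule is recorded as skipped). Boundaries are strict
inequalities. A single pass is the default; re-iteration to a fixed
point is available and converges within a few passes because each rule
is monotone.

The density-inflection threshold fits a Gaussian KDE (Silverman
bandwidth) to `log10(x+1)` and takes the density minimum between the
two highest modes — only when that valley dips below half the lower
mode's density, so KDE wiggles on unimodal data never split it. With
fewer than 50 values, constant input, or no qualifying valley it falls
back to a quantile (0.01/0.99 standalone; 0/1 inside the QC filter so
that a fallback removes nothing and reapplication is idempotent).

## Normalization, variable genes, residualization

UMI counts are pseudo-log normalized, `ln(1 + c·10⁴/total)`; TPM as
`ln(1 + tpm)`. Variable genes are ranked by the residual of a degree-2
fit of log variance on log mean (zero-variance genes never qualify).
Covariate residualization is per-gene OLS with intercept, dropping
later collinear columns, with residuals z-scored per gene and clipped
at ±10 to bound outlier influence.

## Module scores

Bin-matched control scoring: genes are ordered by across-cell mean
expression (ties by gene index — deterministic), split into 25
equal-frequency bins; each present set gene draws 100 control genes
from its bin without replacement (with replacement when the bin is
smaller). The score is the set-gene mean minus the pooled control
mean, per cell. Bin count and control count are conventional defaults
of this scoring family and are exposed in configuration. The score is
invariant to adding a constant to one cell's expression vector and
bitwise reproducible given the seed.

Variants: `minmax` rescales each module to [0,1] over the full joint
cell set (qualitative landscape views juxtapose datasets in one shared
scale; a constant module maps to zeros); `zscaled_by_dataset` centers
and scales (sample SD, ddof 1) each module within each dataset, which
is a precondition for the KS comparison below.

## Annotation

- *Cluster annotator*: per-gene z-scores across cells; lineage score
  of a cluster = Σ over cluster cells of specificity-weighted marker
  z-scores (weight `1/√m` for a gene listed by *m* lineages); argmax
  label unless the top score `< cluster_size/4`; clusters under 3
  cells are unknown.
- *Per-cell annotator*: lineage score = mean marker z-score; assign
  the argmax only if positive and ahead of the runner-up by ≥ 0.25.
- *Reference annotator*: centroids of reference labels on the
  reference's top variable genes; both sides standardized per gene
  with the reference's mean/SD (without this, the shared baseline
  expression profile makes all centroids near-perfectly correlated
  with every cell and nothing clears the delta rule); Spearman
  correlation per query cell; unknown when top − median < 0.05. In the
  pipeline the reference labels are the cluster annotator's labels on
  the designated reference dataset, so no ground truth leaks in.
- *Consensus*: strict 2-of-3 majority; three-way disagreement is
  unknown (`unknown` counts as a vote). PE consensus cells are split
  into PE_I/PE_II by joint-landscape cluster: with an externally
  supplied assignment reproducing the published landscape the
  published subtype-II cluster list applies; on a fresh landscape,
  PE-heavy clusters (≥3 PE cells) with positive mean z-scaled AMN
  module score become PE_II, operationalizing the amnion-signature
  definition of the subtype.

Annotator accuracy on synthetic cohorts is evaluated on
non-intermediate cells (intermediates are planted to be genuinely
ambiguous) among the cells an annotator assigns; the consensus is
required to be within 0.05 of the best single annotator while
assigning ≥ 90% of cells correctly.

Rank-sum markers: two-sided Wilcoxon/Mann–Whitney with normal
approximation and tie correction per group vs rest, after removing
`MT-`/`RPS`/`RPL` genes; genes with all values tied get p = 1. Log
fold change uses the expm1-mean convention
`ln(mean expm1(x)+1) − ln(mean expm1(y)+1)`; BH correction within each
group.

## Composition and association

The contingency table pools datasets by founding source (rows) against
the three primary cell types, optionally plus an unknown column —
giving df 6 and 9 for four sources. Plain Pearson χ², no Yates
correction; empty marginals are an error instructing removal of the
category. PE subtypes are pooled for this table (subtype-resolved
tables available). Dataset clustering is average-linkage agglomeration
on row-normalized proportions with Newick export.

## Joint landscape and distribution distances

Genes present in all datasets are ranked by the median of per-dataset
variable ranks; the top 2000 (or a proportionate cut on small
synthetic universes) are z-scaled per dataset, concatenated and
reduced by PCA (10–15 components; component signs fixed so the
largest-magnitude loading is positive). Clustering is
shared-nearest-neighbor Leiden: kNN (k = 20, self included), Jaccard
neighborhood overlap weights pruned below 1/15,
RB-configuration modularity at resolution 2.0 (high resolution so
small lineages in small datasets still form clusters), seeded, ids
relabeled by decreasing size. This baseline landscape deliberately
replaces published integration machinery; all downstream statistics
are integration-agnostic and accept an external assignment TSV.

JSD defaults to the natural-log Jensen–Shannon divergence (range
[0, ln 2], 0·log 0 := 0); a metric mode returns the base-2 square root,
which satisfies the triangle inequality (property-tested). PCD
restricts each pair to the intersection of supports; pairs with fewer
than 3 shared clusters or a zero-variance restricted vector are
masked undefined (correlation on ≤2 points is degenerate) rather than
raised. Heatmap ordering imputes masked entries with the matrix
maximum for tree building only.

## Bootstrapped KS distances

Within each iteration every dataset contributes one draw (with
replacement, at the smallest dataset's size unless configured —
always derived from the data at hand and recorded) used against *all*
partners, making the averaged matrix exactly symmetric; the diagonal
uses a second independent draw of the same dataset and is reported,
not zeroed — it is the self-resampling null scale, decaying as
c·n^{−1/2} (asserted: the n=100 vs n=400 ratio lies in [1.6, 2.4]).
The KS statistic is evaluated exactly over pooled sorted values. The
sensitivity analysis reruns the bootstrap at sizes
{100, 400, 800, 1000, 1500} and reports difference matrices, Frobenius
norms, and Spearman rank correlations of off-diagonal distances
against the reference size — the scientific claim being that distance
*rankings* are stable even where absolute values drift.

## Pathway activity

Per cell, genes are ranked by decreasing expression with ties broken
by one seeded random permutation (the dominant tie block is
zero-expression genes; a fixed permutation avoids systematic
gene-order bias while keeping results deterministic). With
K = ⌈0.05·n_genes⌉, activity = Σ_{k≤K} hits(k) / Σ_{k≤K} min(k, |S|),
so perfect top-ranking scores 1. The top fraction follows the cited
scoring family's convention; group means leave empty (group, set)
cells missing, never zero.

## Problem sizes and runtime choices

The test suite and acceptance script run the full pipeline on cohorts
of 3–9 datasets with 220–1000 cells each over 600–1200 genes, and the
archetype-recovery analysis on 9 datasets × 1000 cells; bootstrap
analyses use 200–1000 iterations. These sizes keep the whole
validation suite to a few minutes on one CPU while leaving all
statistical conclusions comfortably away from their thresholds; the
generator and pipeline scale linearly in cells × genes.

## Known limitations

- The three annotators are deliberate simplifications of the
  marker-based and reference-based tools they stand in for; fidelity
  to any specific published tool is a non-goal.
- The joint landscape is a shared-gene PCA, not an integration method;
  with strong batch structure, clusters can be partially
  dataset-specific (the PCD shared-cluster restriction exists for
  exactly this situation).
- Pathway gene membership is user-supplied (GO exports change between
  releases); without a GMT file the pipeline scores the lineage marker
  panels as sets.
- TPM generation rescales noisy programs rather than simulating
  transcript-length effects; isoform collapsing is validated on
  synthetic transcript tables only.
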