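# Methods

## Enrichment model

Within each sample, expression values are ranked ascending with average
ranks for ties. For a risk set with n₁ measured genes against n₂
remaining genes, U = R₁ − n₁(n₁+1)/2 where R₁ is the risk group's rank
sum, and the rank-biserial effect size is r = 2U/(n₁n₂) − 1. Risk genes
absent from the measured transcriptome are dropped from the risk group
(logged once per set): the statistic describes the measured transcriptome
only, while Jaccard comparisons between gene sets use the full curated
lists — overlap of curated knowledge is a different question from
overlap of measurable signal.

Significance is one-sided (alternative: risk group ranks higher, i.e.
enrichment; deprivation appears as r < 0 with p near 1) from the normal
approximation with tie-corrected variance and a 0.5 continuity
correction. At transcriptome scale (thousands of genes per sample) the
exact U distribution is unnecessary; the approximation is oracle-checked
against `scipy.stats.mannwhitneyu` and against exhaustive pair counting
at small n in the test suite. Degenerate samples (all values equal)
return r = 0, p = 0.5.

FDR is Benjamini–Hochberg within each gene set across its samples; a
`fdr_scope="global"` flag pools the whole grid instead. Z-scores use the
sample SD (ddof = 1) per set across samples; zero-variance rows map to
z = 0 so degenerate sets cannot poison downstream clustering.

Stage trajectories average r over the samples of each ordered stage and
smooth with an unpadded centered moving average of window 3, so the
output has n_stages − 2 points (11 → 9). Windows touching a stage with
no samples are reported missing rather than computed on a shrunken
window. Hot-spot ranking ties break deterministically: more samples,
then lexicographic region, then earlier stage.

## Trait space

Profiles are compared as rows of the set × sample matrix. Clustering
defaults to complete linkage on Euclidean distances (the defaults of the
standard heatmap-clustering tools); scaling is per set (row Z), with the
per-sample alternative available by passing a differently scaled matrix.
Missing cells are imputed to 0 = null enrichment before distances.
t-SNE uses PCA initialization, perplexity 5 by default (problems here
have tens of sets), 1000 iterations and a fixed seed; the KL divergence
is reported. Identical seeds reproduce coordinates exactly.

## Co-expression network

Genes with total expression below 10 (linear-scale units summed over
samples) are removed; on log-scale inputs the filter should be disabled
(threshold −inf) since row sums are not masses. Optional outlier-sample
exclusion cuts the average-linkage dendrogram of inter-sample Euclidean
distances at a configurable height and keeps the largest cluster; the
height has no universal scale (it depends on units and gene count), so
it is off by default. Pearson correlation is computed on values as
given; a log2(x+1) pre-transform materially changes networks and is left
to the caller's normalization step.

Signed adjacency a_ij = ((1 + cor)/2)^β preserves correlation sign.
β defaults to 7; `pick_soft_power` instead chooses the smallest
candidate whose connectivity distribution fits log p(k) ~ log k with
R² above 0.85 (10 equal-width bins; argmax R² with smallest-power
tie-break if none passes). TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)
+ 1 − a_ij); 1 − TOM is the clustering dissimilarity.

Module detection prunes the average-linkage dendrogram at (1 − gap) of
its top merge height (gap = 0.1): in a soft-thresholded signed network,
joins between unrelated branches sit near the dissimilarity ceiling
(unrelated genes have adjacency ≈ 0.5^β, hence 1 − TOM ≈ 1), so the cut
height adapts to wherever that ceiling is realized. Branches below the
cut with ≥ 40 genes (configurable) become modules, labelled M1, M2, …
by descending size; everything else is unassigned. Pure-noise input
merges almost entirely above the cut and yields no modules. This is a
deliberately simple variant of adaptive dendrogram cutting: it has no
PAM-like reassignment stage and no recursive deep-split, which trades a
little sensitivity to nested module structure for determinism and
auditability. The whole network is computed in one block with a
20,000-gene guard; block-wise approximation (as used for genome-scale
runs elsewhere) can shift module boundaries, so single-block computation
is recorded as a deviation in every run manifest.

Eigengenes are the first right singular vector (unit norm) of the
module's gene-standardized expression, sign-oriented to correlate
positively with the module's mean standardized profile. The orientation
and the fixed unit-norm scale matter downstream: the regression
retention threshold is only meaningful on a common eigengene scale.

## Spatiotemporal regression

Each eigengene is regressed by OLS on treatment-coded region and stage
indicators (no interactions); the declared reference levels are absorbed
into the intercept, so a 12-region × 12-stage vocabulary yields
1 + 11 + 11 columns. Predicted level on the full grid is intercept +
β_region + β_stage (reference βs = 0); the argmax cell is the module's
peak, ties broken by declared level order. A module is retained when its
largest raw coefficient exceeds 0.05 — an effect-size criterion, not a
p-value one, hence no multiple-testing correction on coefficients; a
`standardized` flag switches to standardized betas. Samples outside the
declared vocabularies are dropped with a count logged.

## Annotation

Module × trait enrichment uses the one-sided hypergeometric upper tail
(Fisher's exact test in the enrichment direction) with the network gene
universe — the genes surviving filtering — as background: modules are
defined on that universe, and testing against the whole genome would
inflate enrichment. Bonferroni correction spans all module × trait tests
in a call by default (a per-trait family flag exists); the top three
modules per trait are flagged by descending odds ratio (∞ when b·c = 0
and a·d > 0). Cell-type specificity reuses the rank-biserial machinery
within each cell-type mean-expression column, Z-scored across cell types
within each unit. Over-representation against user-supplied term→gene
tables applies the [3, 500] term-size window before testing and BH
across the tested terms; no ontology content is bundled.

## Imaging correlation

A user-editable match table maps transcriptome atlas regions to
morphometry regions, listing the hemisphere members to average and
marking exclusions with reasons (ventricles are non-parenchymal and
never enter the correlation). Effect sizes are hemisphere-averaged per
retained region and Spearman-correlated (average-rank ties, two-sided p
via the t approximation) with regional enrichment. No spatial-
autocorrelation null (spin test) is implemented — plain Spearman treats
regions as exchangeable, which is a known limitation of this design.

## Synthetic data: what it emulates and what it does not

The generators produce exactly the statistical structure each stage
assumes, with serialized ground truth:

* **Bulk enrichment** — per-gene log-normal baselines (gene locations
  N(1, 1), within-gene noise SD 0.5 on the log scale) over a
  region × stage × donor layout (defaults 6 × 6 × 2 = 72 samples, 2,000
  genes, sized for sub-minute tests). Planted sets get a multiplicative
  exp(δ) boost in their target cells; δ = 2 by default, a strong but not
  saturating rank shift (mean target-cell r ≈ 0.8). The boost is
  multiplicative on raw expression rather than a direct rank injection
  so monotone-invariance properties remain testable.
* **Modules** — member genes are √ρ·factor + √(1−ρ)·noise with
  within-module correlation ρ (default 0.6, a realistic magnitude for
  bulk co-expression) and factors built from additive region/stage
  effects (unit effects, factor noise SD 1). The default module preset
  is 5 modules × 100 genes over 5 regions × 6 stages × 2 donors = 60
  samples. Recovery is scored by ARI over the planted members.
* **Cell types** — signature genes elevated by fold 4 in their type.
* **Morphometry** — effects are built on normal scores of the enrichment
  ranks with Pearson loading 2·sin(π·ρ_s/6), the classical conversion
  giving expected Spearman ρ_s for bivariate normal data; hemisphere
  pairs carry small L/R jitter (SD 0.02) and Cohen's-d-like scale 0.2.

Not emulated: negative-binomial count noise, library-size artifacts,
donor effects, spatial autocorrelation between regions, or the empirical
distributions of any public atlas. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own
assumptions, not performance on real data.

## Problem sizes and numerics

Test and acceptance runs use the preset sizes above; the permutation
calibration uses 2,000 label shuffles of a 500-gene sample (binomial
3-SD band around α = 0.05); hot-spot recovery uses 50 independent
simulations; morphometry calibration 100 draws at n = 38 regions.
Oracle comparisons are exact to ≤ 1e-9. All generator and pipeline
randomness flows from a single seed (per-stage seeds derive by a fixed
offset scheme, documented in `pipeline.py`); module detection and
eigengene extraction are fully deterministic given their inputs.

## Known limitations

Single-block network construction caps at ~20k genes on commodity
memory; the adaptive cut has no deep-split for nested modules; the
enrichment p-value is asymptotic (fine at transcriptome n₁+n₂, checked
at small n); probe-level microarray QC beyond max-collapse and
imputation of missing microarray values are deliberately out of scope
(missing values are a hard error).
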