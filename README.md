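# strisk — spatiotemporal risk-gene expression enrichment

`strisk` implements a pipeline for asking *where in the brain, when in
development, and in which cell types* the genome-wide risk genes of
polygenic neuropsychiatric traits are preferentially expressed. It is
aimed at researchers working with developmental brain transcriptomes
(bulk RNA-seq with region/stage annotations), adult microarray atlases,
single-cell profiles, and case–control structural MRI effect sizes.

## The statistic at the core

For a risk gene set *G* and one transcriptome sample, all measured genes
are ranked by expression; the genes of *G* form the risk group (size *n₁*)
and the rest the control group (*n₂*). With Mann–Whitney statistic *U* of
the risk group, the **rank-biserial correlation**

  r = 2U / (n₁·n₂) − 1 ∈ [−1, 1]

equals P(risk gene outranks control gene) − P(reverse): +1 is complete
enrichment, −1 complete deprivation. One-sided p-values (alternative:
risk group higher) use the tie-corrected normal approximation with a 0.5
continuity correction, with Benjamini–Hochberg FDR within each gene set
across samples. Per-set Z-scoring of r makes profiles comparable across
traits.

On top of this the package provides:

* **hot-spots** — the top-k (region × stage) cells by mean r per set, and
  per-stage trajectories smoothed by an unpadded window-3 moving average
  (11 stages → 9 points);
* **trait space** — hierarchical clustering and seeded t-SNE of the
  per-set enrichment profiles, plus pairwise Jaccard overlap of the gene
  sets themselves (to check clustering is not driven by shared genes);
* **co-expression modules** — signed adjacency ((1+cor)/2)^β at soft
  power β (default 7, or chosen for scale-free fit R² > 0.85),
  topological-overlap dissimilarity (1−TOM), average-linkage clustering
  with adaptive branch pruning (minimum module size 40), and module
  eigengenes (sign-oriented PC1);
* **spatiotemporal regression** — OLS of each eigengene on treatment-coded
  region + stage dummies (12+12 levels → 11+11 dummies in the full human
  configuration), additive predicted grids whose argmax is the module's
  expression peak, and retention of modules with any coefficient > 0.05;
* **annotation** — one-sided Fisher's exact module × trait enrichment
  (Bonferroni across all tests, top-3 modules per trait by odds ratio),
  rank-biserial cell-type specificity, and generic hypergeometric
  over-representation against user-supplied term→gene tables;
* **imaging correlation** — hemisphere-averaged structural effect sizes
  (d_icv) per matched region, ventricles excluded, Spearman-correlated
  with regional enrichment;
* **synthetic data** — generators for every input family with planted,
  serialized ground truth (rank-shift enrichment effects, latent-factor
  modules, cell-type signatures, calibrated morphometry coupling).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with known truth (seed as optional argument):

```sh
python analysis/01_simulate.py 0
python analysis/02_enrichment_hotspots.py
python analysis/04_coexpression_modules.py
python analysis/07_imaging_correlation.py
```

prints (abridged):

```
bulk: 2000 genes x 72 samples (6 regions x 6 stages), 2 planted risk sets (delta=2.0), 3 random controls
enrichment: 5 sets x 72 samples; 4 cells at q<0.05
  planted set RiskA: rank-1 hot-spot matches the planted target cell
  planted set RiskB: rank-1 hot-spot matches the planted target cell
modules: detected 5 modules (sizes {'M1': 100, ...}) from 500 genes
  recovery ARI vs planted truth: 1.000
imaging: 38 matched regions (2 member rows excluded), Spearman rho = -0.517 (p = 8.83e-04); generator target -0.48
```

Reading: the two risk sets planted with a log-scale boost δ = 2 in one
(region, stage) cell each are recovered as the rank-1 hot-spots; the five
planted co-expression modules are recovered exactly (adjusted Rand index
1.0); and the morphometry coupling generated at Spearman −0.48 over 38
regions is estimated at −0.52 for this seed (sampling SD ≈ 0.2 at n=38).
Tables land under `results/`. A `strisk` CLI exposes the same stages for
file-based inputs (`strisk enrich --expr ... --sets ...`, `strisk run`,
etc.), and `strisk.pipeline.run_pipeline` orchestrates a full seeded run
with a checksummed manifest.

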