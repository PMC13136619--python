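# Methods

`codelnet` prioritizes driver-gene candidates inside a recurrent arm-level
co-deletion from single-cell tumor transcriptomes.  The motivating setting is
the oligodendroglioma 1p/19q co-deletion: every tumor cell loses one copy of
both arms, the expression of hundreds of genes drops with dosage, and the
question is which of those genes actually matter for downstream signaling and
immune programs.  The answer offered here is network-based: learn per-gene
regulatory models from tumor cells, propagate each co-deleted gene's
influence through the learned network onto pathway gene sets, and keep genes
whose propagated impact beats degree-matched random networks reproducibly
across tumors.

## Data model

Expression is stored as `x = log2(TPM / f + 1)` with the scale factor `f`
recorded (`f = 1` default; `f = 10` reproduces the log2(TPM/10+1) convention
of some public datasets).  Genes carry a chromosome, an arm (p/q), a start
coordinate, and a per-chromosome `order_index`; all window arithmetic
(smoothing, local predictor exclusion) is measured in retained-gene
positions, so the annotation is re-indexed after every gene filter.

## Stage 1 — preprocessing and cell labels

Genes with aggregate expression `log2(mean TPM + 1) < 4` are removed
(boundary retained).  Cell subpopulations come from a 2-D UMAP embedding
(default settings, fixed seed, convention 123) whose coordinates are min-max
standardized per axis; cells split at the midlines: scaled y < 0.5 is the
large tumor subpopulation SP1, y > 0.5 the small nontumor subpopulation SP2,
and optionally x > 0.5 under y < 0.5 a subclone SP3.  Boundary cells go to
the "greater" side — a measure-zero case fixed for determinism.  Known
outlier cells can be excluded by explicit id list; no automatic outlier rule
is invented.  Precomputed label tables are accepted in place of the
embedding.

## Stage 2 — expression-derived copy number

Per gene, expression is centered across cells and clipped to ±3; per
chromosome, a centered rolling mean over 51 genes (25 on each side; only
full windows) yields a smoothed profile.  Reference cells are selected by a
per-cell one-sided Welch test on the *original* expression values of
affected-arm versus sister-arm genes; cells with p ≥ 0.99 (inclusive) are
deemed co-deletion-free.  The reference-average profile is subtracted and
values within ±0.2 (inclusive) are set to 0.  Gene-level estimates average
all windows overlapping the gene; genes covered by no window get 0 with an
explicit coverage flag so they can still serve as neutral covariates.

The 51-gene window resolves an internal ambiguity of the usual description
("window of 50 neighboring genes, 25 down- and 25 upstream"): 25 + 25 + the
center gene is taken literally; the width is configurable.

## Stage 3 — differential expression and enrichment

Each gene is tested between SP1 and SP2 using only the cells in which it was
measured (value > 0; at least 2 per group, otherwise the gene is omitted
with a reason code).  Variances are moderated by empirical Bayes: prior
degrees of freedom `d0` and prior variance `s0²` are estimated by a method
of moments on the log sample variances (digamma/trigamma moment matching,
per-gene residual df), the posterior variance is
`s̃² = (d0·s0² + d·s²)/(d0 + d)`, and the moderated t has `d0 + d` df.  With
`prior_df = 0` the statistic reduces exactly to the pooled-variance t.  The
log fold change is the difference of nonzero-cell means (the same cells the
test uses).  DE genes (q ≤ 0.01 and |logFC| ≥ 2, both inclusive) are tested
per pathway for enrichment with one-sided Fisher exact tests, separately for
under- and overexpressed genes, BH-corrected across pathways, significant at
q < 0.05 (strict).  The enrichment universe is all tested genes.  This is a
reimplementation of the standard moderated-t workflow; gene counts on real
data may differ marginally from the original package.

## Stage 4 — regulatory network inference

Tumor (SP1) cells are split 2/3 train / 1/3 test, repeated for
`n_network_instances` independent instances.  Genes with variance < 0.5
across the analysis cells are dropped (the regression cannot explain flat
genes).  Each remaining gene is modeled over the training cells as a linear
combination of (a) the expression of all genes outside ±50 order positions
on its own chromosome — the exclusion zone prevents smoothing-window dosage
leakage from masquerading as regulation — and (b) its own copy-number
estimate.  Predictors are standardized with train-set statistics.

Selection runs along the lasso (LARS) regularization path, capped at
`min(n_train − 2, 50)` steps.  Each predictor entering the path receives a
covariance-test p-value: the drop in covariance between the full lasso fit
and the fit on the previously active set, both evaluated at the next knot,
referenced against Exp(1); the noise scale is the residual variance at the
5-fold cross-validation-selected penalty (`RSS/(n − df − 1)`).  P-values are
BH-adjusted within the model; predictors with q ≤ 0.01 are kept and their
coefficients re-estimated by OLS (penalty-free, hence independent of where
on the path they are read).  All of this is computed from precomputed
inner-product (Gram) matrices shared across the per-gene subtasks; the
reduced-model lasso solutions use an active-set KKT solver warm-started from
the path (with a full path solve as fallback).  Memory grows with the square
of the gene count; the intended scale is a few thousand genes.

Validation predicts the held-out cells from the train-standardized
predictors and correlates per gene (undefined for constant predictions;
flagged and excluded from medians).  Baselines are degree-preserving random
networks: directed double-edge swaps (10·|E| successful swaps) that forbid
self-loops, duplicate edges, and exclusion-zone edges, with each coefficient
traveling with its source; copy-number covariates are reassigned uniformly
preserving their count.  The original-versus-random comparison of per-gene
median test correlations uses the one-sided Wilcoxon signed-rank test (the
standard paired rank test; "paired one-sided U test" in the field's
shorthand).

## Stage 5 — propagation and candidate statistics

The propagation graph weights each expression edge `u→v` by
`|coefficient| · max(0, r_v)` where `r_v` is the target's test-set
prediction quality; copy-number covariates do not propagate.  The impact of
source `s` on target `t` is the sum of these products over all directed
paths up to length 5 (configurable), computed by accumulating matrix powers
with an early-stop tolerance of 1e-8.  Negative correlations are treated as
non-informative (weight 0) rather than sign-flipping.  The exact propagation
formula of the originating toolchain is not published at this level of
detail; the contract implemented here preserves its stated properties —
path-based, direct plus indirect, quality-weighted, nonnegative, comparable
across degree-matched permutations — and a direct-effects-only variant
(path cap 1) is provided.

Per source gene on the affected arms and per pathway class (signaling,
immune), impacts are summed over the measured genes of the class union
(target ≠ source).  Each instance's observed total is paired with the mean
total under that instance's 10 random networks (quality recomputed on the
same test cells); across the 10 instances a paired one-sided t-test (df
n−1; a Welch correction is undefined for paired designs) yields per-gene
p-values, BH-corrected per tumor and per class.  Candidates require q ≤ 0.1
(inclusive) in ≥ 2 tumors and a consistent SP1-versus-SP2 fold-change sign
across all tumors where the gene is measured (sign-only; no significance
threshold on the direction call).  Two results-level analyses are included:
a rank-permutation test for whether candidates sit atop the region's DE
ranking (plain `hits/n_perm` estimator; +1 correction by flag) and a
one-sided Welch comparison of candidate versus non-candidate impacts.

## Synthetic data generator

The generator emulates what the pipeline depends on and nothing more: an
artificial genome (default 4 chromosomes × 100 genes, p/q arms of 50,
evenly spaced), a sparse random regulatory DAG (60 edges, |β| ∈ [0.4, 1]
with random sign) respecting the ±50 exclusion zone so the inference model
class can represent it, linear structural-equation expression with Gaussian
noise (σ = 0.3), a hemizygous co-deletion (default chr1p + chr4q) carried by
a 400-cell tumor majority beside 60 normal cells, and optional dropout.

Dosage has two deliberate components.  A uniform `deletion_shift` (0.6 log2
units) lowers *every* deleted-arm gene in tumor cells — the arm-wide
footprint the copy-number stage must recover; 30% of deleted-arm genes
additionally carry a gene-specific dosage coefficient α ∈ [0.3, 0.8], the
regulatory-scale signal the network stage must attribute to the copy-number
covariate rather than to other genes.  With only the sparse α-effects the
arm-level footprint would average ~0.17 log2 units and vanish inside the
±0.2 zero band, leaving the copy-number stage nothing to detect; the
uniform shift is what hemizygosity does in real data.

Affected arms receive a baseline elevation (0.85 log2 units), pinned exactly
by recentring the arm-set means: the reference-cell rule (Welch p ≥ 0.99)
can only single out non-deleted cells when, as in the motivating dataset,
the co-deleted arms carry genes at least as highly expressed as their
sister arms; with arm-balanced baselines every cell's p-value concentrates
near 0.5 and no cell ever reaches 0.99.  Fixing the contrast removes a
finite-genome lottery that would otherwise make reference selection fail on
a fraction of seeds for reasons unrelated to the method.

What the generator does *not* emulate: count-level noise (no negative
binomial), batch effects, doublets, cell-size/library variation, nonlinear
regulation, feedback loops.  Passing tests therefore demonstrate the
correctness and calibration of the implemented procedures under the stated
generative model — not that the model captures all properties of real
single-cell data.

## Evaluation conventions

* **Skeleton-level edge recovery.**  The per-target linear models capture
  statistical dependencies: a child predicts its parent exactly as well as
  the reverse, so roughly half of all recovered links are orientation
  reversals of true edges.  Precision and recall are therefore evaluated on
  the undirected skeleton; coefficient RMSE uses only correctly oriented
  edges.  Directed evaluation of the same runs roughly halves precision
  purely through reversals.
* **Learning set for the recovery study.**  The simulation recovery study
  fits models on all simulated cells (tumor and normal) with the true
  copy-number covariate: within a tumor-only cell set the true covariate is
  the constant −1 and carries no information.  The data-analysis path
  instead learns on SP1 cells with *inferred* copy-number estimates, which
  vary from cell to cell.
* **Problem sizes.**  The shipped studies use the generator defaults
  (400 genes, 460 cells) for network and copy-number recovery; the
  end-to-end determinism check runs a two-tumor preset at 320 genes,
  240 cells, 2 instances × 2 permutations; the planted-impact study uses
  160-gene genomes with directly assembled network instances (it tests the
  propagation statistics, not learning).  The preset lowers the variance
  cutoff to 0.05 because the generator's within-tumor variance is σ² ≈ 0.09
  by construction, two orders below real single-cell spread.

## Numerical choices and degenerate inputs

* Ties: gene order ties at equal start coordinate break lexicographically;
  boundary cells at 0.5 go to the "greater" subpopulation; all stated
  thresholds are inclusive except enrichment significance (strict <).
* Zero-variance targets, empty predictor sets, and constant copy-number
  covariates yield intercept-only models with flags, never a failed run.
* A cell set in which both arm groups have zero variance gets Welch p of 1
  (equal means) or 0/1 by sign, documented in the function contract.
* Degenerate paired tests: all-zero differences give p = 1; a constant
  positive shift gives p = 0 with a flag.
* Entries that cannot be assessed on a truncated lasso path are reported at
  p = 1 (conservative).
* All randomness flows from a single master seed through named
  `SeedSequence` derivations (stage, tumor index, instance index), so reruns
  are bit-identical and independent of worker count.

## CLI

The library functions are the primary interface.  The CLI wraps the stages a
user runs from a shell — `simulate`, `cnv`, `de`, `learn-net`, `propagate`,
`run-all`, `run-variant`; the remaining spec'd stages are single library
calls exercised by `run-all`.

## Known limitations

* Edge direction is not identifiable from observational equilibrium data;
  links are dependencies, not causal claims.
* The Gram-matrix strategy trades memory for speed; genome-scale runs
  (tens of thousands of genes) would need a streaming variant.
* The covariance test's Exp(1) reference is asymptotic and assumes
  normal-ish errors; with heavy zero inflation (no imputation) its p-values
  become conservative.
* Real-data replication of the motivating study is compute-scale (hundreds
  of CPU-hours per network instance were reported for the original
  analysis) and requires external downloads; it is outside the shipped test
  suite.
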