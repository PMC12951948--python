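# Methods

## Scoring model

All methods operate on a preprocessed cells × genes matrix X of
log-transformed, library-size-normalized expression (unitless, nonnegative).
Gene and cell identifiers are opaque, case-sensitive strings matched
verbatim; signature genes absent from the matrix are dropped with a logged
report rather than raising, so signatures curated on other references remain
usable — the intersection is always reported.

### Tirosh family

A cell's score is the mean over signature genes of (expression − mean
control expression). The four control strategies differ only in how the
control sets C_s are built from the per-gene average expression profile ḡ
(sorted nondecreasing; ties keep original gene order via a stable sort,
which makes every downstream selection deterministic):

* **bin_sampled** (`seurat`, `scanpy_bins`): ḡ is split into `n_bins` (default
  25) contiguous rank bins of equal size; each signature gene receives c
  (default 100) non-signature genes sampled uniformly without replacement
  from its bin. When p mod n_bins ≠ 0 the extra genes go to the
  lowest-expression bins (sizes differ by at most one; any fixed convention
  works, this one is pinned). `seurat` samples per signature gene;
  `scanpy_bins` pools the eligible genes of all touched bins and samples one
  shared control set — both behaviors exist in the wild, so both are exposed.
  Sampling is the only source of randomness in the package and is
  reproducible from `ControlConfig.random_seed`.
* **bin_all_genes** (`seurat_ag`): every non-signature gene of the bin; c is
  ignored, control sets vary in size.
* **bin_least_variable** (`seurat_lvg`): the c genes of the bin with smallest
  dispersion. Dispersion is the "seurat-flavor" normalized dispersion
  (variance/mean of the expm1-transformed values, log-dispersions z-scored
  within 20 bins of log1p mean expression). Numerically constant genes
  (variance/mean ≤ 1e-12) rank first — they are the least variable by any
  reading — and genes with undefined dispersion rank last. The raw
  variance/mean ratio is available via `use_normalized_dispersion=False` for
  sensitivity checks; an agreement test against the scanpy implementation of
  the same statistic guards the in-package computation.
* **ans**: signature genes in the top ⌊c/2⌋ of the all-genes expression
  ranking are excluded first (reported with reason codes; if the whole
  signature is excluded, the error advises shrinking the control size or
  extending the signature). Each retained gene receives the contiguous
  window of c genes of the signature-excluded sorted profile g̃ whose mean
  is closest to the gene's ḡ_s. Window means of a sorted profile are
  nondecreasing, so the absolute distance is unimodal and the leftmost
  argmin (NumPy's first-minimum convention) is both the exact optimum and
  the tie-break toward lower expression. Ranking for the exclusion uses the
  all-genes profile — the stricter reading — and boundary ties resolve by the
  stable sort order.

Tirosh-family scores are invariant under adding a constant to every gene of
a cell (signature and control means shift equally), but not under cell
deletion, since ḡ and hence the control sets depend on the dataset —
which is exactly why joint scoring across samples is recommended.

### Rank-based scorers

* **UCell**: within each cell all p genes are ranked by decreasing expression
  with averaged ties; ranks beyond `max_rank` (default 1500) are clamped to
  `max_rank + 1`. U = Σ r_s − m(m+1)/2 and score = 1 − U/(m·max_rank) ∈
  [0, 1]. Scores depend only on the cell's own ranks, so adding or removing
  cells never changes existing scores.
* **JASMINE**: per cell, the mean rank of expressed (nonzero) signature genes
  among expressed genes (ascending by expression, averaged ties), divided by
  the number of expressed genes, plus an enrichment value from the per-cell
  2×2 expressed/signature table — odds ratio a·h/(b·g) or likelihood
  a·(g+h)/(g·(a+b)). Both components are min–max normalized across all
  cells of the dataset (whole-dataset scope, which is what makes the method
  composition-sensitive) and averaged. Degenerate cells are handled
  explicitly: a = 0 yields enrichment 0; a > 0 with a zero denominator
  yields the maximum enrichment observed among well-defined cells, or 1 when
  that maximum is not positive, keeping scores finite and monotone in a; a
  zero-range component normalizes to zeros with a warning.

## Annotation and its metrics

Cells are labeled by the argmax over signature score columns (ties go to the
first signature in input order and are counted). Argmax labeling is
invariant to any strictly increasing transformation applied jointly to all
columns but *not* to per-column shifts — the property that motivates
matching score ranges across signatures. Two quantities disentangle
information content from range comparability:

* **information quantity**: mean held-out balanced accuracy of an unpenalized
  multinomial logistic regression (lbfgs, `C=inf`, tol 1e-6, iteration cap
  2000) predicting the true label from the score columns under stratified
  10-fold cross-validation (shuffled, seed 42 by default). Multinomial
  rather than one-vs-rest because the labels are mutually exclusive states;
  the solver settings are pinned for reproducibility.
* **scale imbalance**: |information quantity − balanced accuracy of the
  argmax labels|. Scores can be informative (high IQ) yet misassign cells
  under argmax when one signature's scores sit on a shifted scale.

Balanced accuracy is the unweighted mean of per-class recall; weighted F1
the support-weighted mean of per-class F1; AUCROC uses the averaged-ties
rank statistic (exactly the Mann–Whitney identity U/(n₁n₂)); AUCPRC is the
average-precision form of the PR-curve area.

## Synthetic data

The generator emulates the features of real log-normalized scRNA-seq data
that scoring is sensitive to, not full count-level realism:

* per-gene baseline means drawn log-normal (default location 0, scale 1) —
  the long right tail is what widens the top expression bin and creates the
  control-selection problem in the first place;
* cell types defined by disjoint (optionally overlapping) marker blocks
  multiplied by 2^log2FC (default log2FC = 2) in their own type;
* multiplicative log-normal noise per cell and gene (default sd 0.3);
* dropout as independent Bernoulli zeroing (default rate 0.3, matching
  mid-range sparsity of real datasets; a preset with rate 0.9 reproduces the
  ~90% sparsity of the hardest real data). An optional mean-dependent
  variant zeroes low-expression genes preferentially;
* samples and batches: each sample carries per-type cell counts, and each
  batch a `depth_factor`. A uniform per-cell depth factor would be removed
  exactly by library-size normalization, so the factor is applied per gene
  as depth_factor^u_g with u_g ~ U(0,1) drawn once per dataset — a
  chemistry-like capture-efficiency profile that survives normalization,
  with depth_factor = 1 an exact null;
* finally cells are library-size normalized to the median depth and
  log1p-transformed.

Everything is reproducible bit-for-bit from the config seed.

What passing tests on these data do *not* show: robustness to ambient RNA,
doublets, UMI count noise, gene–gene correlation structure, or real
batch-effect geometry; marker fold-changes here are homogeneous within a
signature, unlike curated signatures whose genes vary in effect size.

## Benchmark procedures and fixture choices

Problem sizes below are the package's default study conditions; all
benchmarks accept user data.

* **Control-bias scan**: homogeneous data (1 type, 1000 cells × 2000 genes,
  dropout 0.3), every gene in the top 8% by mean expression scored as a
  single-gene signature by each method. On homogeneous data the expected
  score is zero, so the per-gene mean score *is* the selection bias. ANS
  cannot score genes inside its exclusion zone; they are reported as
  unscorable rather than silently skipped. At this scale (80 genes per bin <
  c = 100) the three bin-based strategies all fall back to whole-bin
  controls and coincide; their bias stays an order of magnitude above the
  neighborhood strategy's regardless.
* **Joint vs per-sample scoring**: cohorts of 6 samples (150 cells each) in
  two batch groups with a capture-efficiency shift (factor 1.5), malignant
  fractions varying across samples (0.3–0.7) the way real cohorts vary —
  this composition variability is precisely what per-sample scoring couples
  into the scores. Variance of per-sample mean malignant-cell scores is
  compared between modes over 20 replicate cohorts. The batch test
  (two-sided Mann–Whitney U on sample means) is calibrated under a no-shift
  null with 10 samples per cohort: with 3-vs-3 samples the exact p-value
  grid is too coarse (five attainable values) for a meaningful calibration
  check, so the null uses 5-vs-5.
* **Noise robustness**: 100-gene marker signature on 2 × 400 cells × 4000
  genes, log2FC 2, dropout 0.1 (strong markers, low dropout). Replacement
  levels run every 5 genes from 0 to 100 over 20 runs — each run fixes a
  random replacement order and pool draw, so corruption is nested within a
  run. The 4000-gene pool matters: with fewer genes the 200 marker genes at
  4× expression shift library-size normalization enough to bias the AUC of
  fully random signatures by up to ~0.06, a fixture artifact rather than a
  scoring property.
* **Signature-length sweep**: genes unusable for control construction (the
  ⌊c/2⌋ lowest or highest expressed) are removed first; the ranked list is
  then extended one gene at a time until AUCROC reaches 1 (non-separating
  lists return the full length, flagged).
* **Marker selection**: per class, a two-sided Mann–Whitney test (exact U,
  asymptotic tie-corrected p) of class vs rest per gene, Benjamini–Hochberg
  adjustment, filters p_adj < 0.05 and log2FC > 0, ranking by ascending
  adjusted p with descending log2FC as tie-break. log2FC is
  log2((mean expm1 + 1e-9)_class / (mean expm1 + 1e-9)_rest), the standard
  convention of single-cell marker-ranking routines, pinned here.

## Numerical choices

* Sparse and dense storage give identical results; sparse matrices are
  sliced column-wise via CSC and densified only for the block in use.
* ANS window means are computed from one cumulative sum (O(p) per
  signature); since window means are nondecreasing, the first-minimum
  convention of `argmin` implements the leftmost tie-break exactly.
* Score TSVs are written at 17 significant digits so a round-trip never
  perturbs downstream argmax decisions; CSV reads use the round-trip float
  parser for the same reason.
* Scores are validated finite; NaN anywhere in a score matrix is an error,
  not a silent drop.

## Limitations

* Control selection operates on the same matrix being scored; there is no
  support for freezing control assignments from a reference dataset.
* JASMINE's min–max normalization makes its scores depend on dataset
  composition by construction; per-batch normalization scopes are not
  implemented.
* The generator's independent-Bernoulli dropout ignores the empirical
  mean–dropout relationship unless the logistic variant is enabled, and its
  batch model is a one-parameter efficiency profile, far simpler than real
  chemistry differences.
* AUCPRC is the average-precision estimator; step-interpolated variants
  differ slightly on tiny datasets.
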