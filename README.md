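# anscore

Gene-signature scoring for single-cell RNA-seq, built around **Adjusted
Neighborhood Scoring (ANS)**, with the classic control-gene strategies, the
rank-based scorers UCell and JASMINE, score-based cell-type/state annotation,
and a benchmark suite that runs on synthetic data with known ground truth.

## The problem

A gene signature S = {s₁, …, sₘ} is a set of marker genes standing in for a
cell type, state, or pathway. Tirosh-style scoring summarizes a cell j's
activity of S on a log-normalized expression matrix X ∈ ℝ≥0^(n×p) as

    score_j = (1/m) Σ_{s∈S} ( X_{j,s} − (1/|C_s|) Σ_{k∈C_s} X_{j,k} )

where C_s is a set of *control genes* with average expression matched to
signature gene s. Subtracting the control mean removes cell-intrinsic
technical variation (capture depth, complexity). Everything hinges on how
C_s is chosen. The classic approach ranks genes by average expression ḡ,
splits them into 25 equally sized bins, and samples c controls from each
signature gene's bin. Because per-gene mean expression is long-tailed, the
top bin spans a huge expression range, and controls drawn from it are badly
matched — single-gene scores of highly expressed genes become systematically
biased, score ranges stop being comparable across signatures, and
argmax-based annotation misassigns cells.

ANS instead selects, for each signature gene s, the contiguous window of c
non-signature genes (on the expression-sorted profile g̃ that excludes S)
whose mean average expression is closest to ḡ_s:

    C_s = argmin_{C_k} | ḡ_s − (1/c) Σ_{g∈C_k} ḡ_g |

Signature genes ranked within the top ⌊c/2⌋ of average expression are
excluded (and reported), because no expression-matched neighborhood can be
centered on them.

Also implemented, for comparison and because they are useful in their own
right: bin-sampled controls (per-gene and pooled variants), all-genes-in-bin
controls, least-variable-in-bin controls (seurat-flavor dispersion), UCell
(per-cell Mann–Whitney U on gene ranks), and JASMINE (mean expressed-gene
rank combined with an odds-ratio or likelihood enrichment).

## Worked example

Generate a synthetic dataset (3 cell types × 200 cells, 20 disjoint marker
genes per type upregulated ~4-fold, 30% dropout), then score the marker
signatures with ANS and annotate each cell by its highest-scoring signature:

```sh
anscore generate --out-dir demo --n-genes 1000 --cells-per-type 200 \
    --n-types 3 --markers-per-type 20 --seed 0
anscore score --matrix demo/expression.csv --signatures demo/markers.gmt \
    --metadata demo/metadata.tsv --method ans --seed 0 \
    --out demo/scores.tsv --annotate
```

which logs

```
INFO anscore: wrote 600 cells × 3 signature scores (ans) to demo/scores.tsv
INFO anscore: wrote annotation report to demo/scores.annotation.tsv
INFO anscore: wrote metrics to demo/scores.metrics.json
```

`demo/scores.tsv` holds one score per cell and signature — positive when the
cell expresses the signature above its expression-matched controls, around
zero otherwise:

```
cell_id	typeA	typeB	typeC
c00000	0.68542174200302664	-0.19465826728010591	-0.36242188530918018
c00001	0.12148643031227564	-0.21720316341916657	-0.12358422685332301
```

and `demo/scores.metrics.json` compares the argmax labels against the
generator's ground truth:

```json
{
  "balanced_accuracy": 0.9966666666666667,
  "weighted_f1": 0.9966666562499349
}
```

i.e. unsupervised score-based annotation recovers the true cell types for
99.7% of cells (balanced over classes). A provenance JSON (method,
parameters, seed, input digests, excluded signature genes) is written next
to every score file.

The same pipeline is available as a library:

```python
from anscore import (SyntheticConfig, generate_dataset, score_all,
                     argmax_labels, evaluate_labels)

ds = generate_dataset(SyntheticConfig(seed=0))
scores = score_all(ds.matrix, list(ds.signatures.values()), "ans")
print(evaluate_labels(argmax_labels(scores), ds.labels).balanced_accuracy)
```

## Benchmarks

`anscore.benchmarks` implements four experiments that probe the failure
modes separating scoring methods, all runnable on synthetic or user data:

* `control_bias_scan` — single-gene scores on homogeneous data should
  average zero; deviations expose control-selection bias.
* `joint_vs_per_sample` — per-sample scoring couples scores to sample
  composition; the variance of per-sample mean scores and a two-sided
  Mann–Whitney U test between batch groups quantify it.
* `signature_length_sweep` — minimal prefix of a ranked marker list whose
  scores reach AUCROC 1.
* `noise_robustness` — AUCROC as signature genes are progressively replaced
  by uninformative genes.
* `select_markers_wilcoxon` — per-class marker signatures via rank-sum
  testing with Benjamini–Hochberg correction.

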