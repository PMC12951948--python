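"""Benchmark procedures for signature scoring methods.

Four experiments probe the failure modes that distinguish scoring methods:

* :func:`control_bias_scan` — on homogeneous data every single-gene score
  should average zero; systematic deviation for highly expressed genes
  exposes control-selection bias.
* :func:`joint_vs_per_sample` — scoring samples individually couples scores
  to per-sample composition; scoring jointly shares one control assignment.
  The variance of per-sample mean scores and a two-sided Mann–Whitney U test
  between batch groups quantify the difference.
* :func:`signature_length_sweep` — the minimal prefix of an
  importance-ranked gene list whose scores separate two classes perfectly
  (AUCROC = 1).
* :func:`noise_robustness` — AUCROC as signature genes are progressively
  replaced by uninformative genes.

:func:`select_markers_wilcoxon` builds per-class marker signatures by
rank-sum testing (class vs rest), Benjamini–Hochberg correction, and log2
fold-change filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu

from . import controls as ctrl
from .annotation import binary_auc
from .core import (
    ControlConfig,
    ExpressionMatrix,
    GeneSignature,
    ValidationError,
)
from .scoring import TIROSH_METHODS, score_signature

logger = logging.getLogger(__name__)

__all__ = [
    "control_bias_scan",
    "JointVsPerSampleResult",
    "joint_vs_per_sample",
    "SweepResult",
    "signature_length_sweep",
    "noise_robustness",
    "select_markers_wilcoxon",
    "select_noise_pool",
    "save_benchmark",
]


def control_bias_scan(
    matrix: ExpressionMatrix,
    methods: list[str],
    top_fraction: float = 0.08,
    config: ControlConfig | None = None,
) -> pd.DataFrame:
    """Score every gene of the top expression fraction as its own signature.

    Returns a tidy table (one row per gene × method, genes in increasing
    mean expression) with the mean and standard deviation of the single-gene
    scores across cells. Genes a method cannot score (ANS exclusion zone)
    have ``scorable=False`` and NaN statistics. Meant for homogeneous
    (single-cell-type) input, where the expected score is zero.
    """
    config = config or ControlConfig()
    profile = ctrl.mean_expression(matrix)
    p = len(profile)
    n_top = int(round(p * top_fraction))
    if n_top < 1:
        raise ValidationError(f"top_fraction={top_fraction} selects no genes (p={p})")
    scan_genes = profile.gene_ids[p - n_top :]
    scan_means = profile.means[p - n_top :]

    rows = []
    for method in methods:
        for rank, (gene, gmean) in enumerate(zip(scan_genes, scan_means)):
            sig = GeneSignature(name=gene, genes=[gene])
            try:
                scores, _ = score_signature(matrix, sig, method, config=config, profile=profile)
            except ValidationError:
                rows.append(
                    dict(gene=gene, method=method, rank=rank, mean_expression=gmean,
                         mean_score=np.nan, sd_score=np.nan, scorable=False)
                )
                continue
            rows.append(
                dict(gene=gene, method=method, rank=rank, mean_expression=gmean,
                     mean_score=float(scores.mean()), sd_score=float(scores.std(ddof=1)),
                     scorable=True)
            )
    return pd.DataFrame(rows)


@dataclass
class JointVsPerSampleResult:
    summary: pd.DataFrame  # mode × sample × batch × label → mean score, n cells
    variance: dict  # (mode, label) → variance of per-sample mean scores
    batch_pvalues: dict  # mode → two-sided Mann–Whitney U p-value (or None)
    tested_label: str = ""


def joint_vs_per_sample(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    method: str,
    config: ControlConfig | None = None,
    label_column: str = "label",
    sample_column: str = "sample_id",
    batch_column: str = "batch_id",
    tested_label: str | None = None,
    max_rank: int = 1500,
) -> JointVsPerSampleResult:
    """Compare scoring all samples together vs each sample individually.

    For each mode, per-sample per-label mean scores are tabulated; their
    variance across samples measures composition sensitivity, and a
    two-sided Mann–Whitney U test compares the ``tested_label`` sample means
    between the two batch groups (skipped unless exactly two batches with
    ≥2 usable samples each).
    """
    meta = matrix.cell_metadata
    if meta is None or sample_column not in meta:
        raise ValidationError("matrix needs cell_metadata with a sample column")
    samples = meta[sample_column].astype(str).to_numpy()
    labels = meta[label_column].astype(str).to_numpy() if label_column in meta else np.array(["all"] * matrix.n_cells)
    batches = meta[batch_column].astype(str).to_numpy() if batch_column in meta else np.array(["batch_0"] * matrix.n_cells)
    uniq_samples = sorted(set(samples))
    if len(uniq_samples) < 2:
        raise ValidationError("joint_vs_per_sample needs at least 2 samples")
    if tested_label is None:
        tested_label = sorted(set(labels))[0]

    per_cell = {}
    joint_scores, _ = score_signature(matrix, sig, method, config=config, max_rank=max_rank)
    per_cell["joint"] = joint_scores
    indiv = np.full(matrix.n_cells, np.nan)
    for s in uniq_samples:
        mask = samples == s
        sub = matrix.subset_cells(mask)
        try:
            sc, _ = score_signature(sub, sig, method, config=config, max_rank=max_rank)
        except ValidationError as err:
            logger.warning("sample %r could not be scored individually: %s", s, err)
            continue
        indiv[mask] = sc
    per_cell["per_sample"] = indiv

    rows = []
    sample_batch = {s: batches[samples == s][0] for s in uniq_samples}
    for mode, vec in per_cell.items():
        for s in uniq_samples:
            for lab in sorted(set(labels)):
                mask = (samples == s) & (labels == lab)
                vals = vec[mask]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    logger.warning("sample %r has no scorable %r cells; dropped", s, lab)
                    continue
                rows.append(dict(mode=mode, sample=s, batch=sample_batch[s],
                                 label=lab, mean_score=float(vals.mean()), n_cells=int(vals.size)))
    summary = pd.DataFrame(rows)

    variance = {}
    for (mode, lab), grp in summary.groupby(["mode", "label"]):
        variance[(mode, lab)] = float(grp["mean_score"].var(ddof=1))

    batch_pvalues: dict[str, float | None] = {}
    for mode in per_cell:
        sub = summary[(summary["mode"] == mode) & (summary["label"] == tested_label)]
        groups = [g["mean_score"].to_numpy() for _, g in sub.groupby("batch")]
        if len(groups) == 2 and min(len(g) for g in groups) >= 2:
            batch_pvalues[mode] = float(
                mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue
            )
        else:
            batch_pvalues[mode] = None
    return JointVsPerSampleResult(
        summary=summary, variance=variance, batch_pvalues=batch_pvalues,
        tested_label=tested_label,
    )


@dataclass
class SweepResult:
    min_length: int
    separating: bool
    aucs: list[float] = field(default_factory=list)
    usable_genes: list[str] = field(default_factory=list)


def signature_length_sweep(
    matrix: ExpressionMatrix,
    ranked_genes: list[str],
    truth_binary,
    method: str,
    config: ControlConfig | None = None,
    max_rank: int = 1500,
) -> SweepResult:
    """Smallest prefix of an importance-ranked gene list reaching AUCROC = 1.

    For control-based methods, genes for which no valid control set exists —
    those among the ⌊c/2⌋ smallest or highest expressed genes — are removed
    before sweeping. Computation stops at the first prefix with AUCROC 1; if
    none separates, the full usable length is returned flagged.
    """
    if not ranked_genes:
        raise ValidationError("ranked gene list is empty")
    truth = np.asarray(truth_binary)
    if len(np.unique(truth)) != 2:
        raise ValidationError("truth must have exactly two classes")
    config = config or ControlConfig()

    usable = [g for g in ranked_genes if matrix.has_gene(g)]
    if method in TIROSH_METHODS:
        profile = ctrl.mean_expression(matrix)
        half = config.control_size // 2
        p = len(profile)
        forbidden = set(profile.gene_ids[:half]) | set(profile.gene_ids[p - half :])
        usable = [g for g in usable if g not in forbidden]
    if not usable:
        raise ValidationError("no usable genes after removing control-infeasible genes")

    aucs = []
    for length in range(1, len(usable) + 1):
        sig = GeneSignature(name="sweep", genes=usable[:length])
        scores, _ = score_signature(matrix, sig, method, config=config, max_rank=max_rank)
        auc = binary_auc(scores, truth, kind="roc")
        aucs.append(auc)
        if auc >= 1.0 - 1e-12:
            return SweepResult(min_length=length, separating=True, aucs=aucs, usable_genes=usable)
    return SweepResult(
        min_length=len(usable), separating=False, aucs=aucs, usable_genes=usable
    )


def noise_robustness(
    matrix: ExpressionMatrix,
    pure_sig: GeneSignature,
    noise_pool: list[str],
    truth_binary,
    method: str,
    n_runs: int = 20,
    seed: int = 0,
    levels: list[int] | None = None,
    config: ControlConfig | None = None,
    max_rank: int = 1500,
) -> pd.DataFrame:
    """AUCROC of progressively noise-corrupted signatures.

    Each run fixes a random replacement order of the signature positions and
    a random draw (without replacement) of pool genes; at level k the first k
    positions are replaced, so corruption is nested within a run. Returns one
    row per run × level with the AUCROC. Deterministic given ``seed``.
    """
    m = len(pure_sig.genes)
    overlap = set(noise_pool) & set(pure_sig.genes)
    if overlap:
        raise ValidationError(f"noise pool overlaps the signature: {sorted(overlap)[:5]}")
    if len(noise_pool) < m:
        raise ValidationError(f"noise pool ({len(noise_pool)}) smaller than signature ({m})")
    truth = np.asarray(truth_binary)
    if len(np.unique(truth)) != 2:
        raise ValidationError("truth must have exactly two classes")
    if levels is None:
        levels = list(range(m + 1))
    if any(k < 0 or k > m for k in levels):
        raise ValidationError("levels must lie in 0..m")

    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        order = rng.permutation(m)
        picks = rng.choice(len(noise_pool), size=m, replace=False)
        for k in levels:
            genes = list(pure_sig.genes)
            for i in range(k):
                genes[order[i]] = noise_pool[picks[i]]
            sig = GeneSignature(name=f"{pure_sig.name}_noise{k}", genes=genes)
            scores, _ = score_signature(matrix, sig, method, config=config, max_rank=max_rank)
            rows.append(dict(run=run, n_replaced=k, frac_replaced=k / m,
                             auc=binary_auc(scores, truth, kind="roc")))
    return pd.DataFrame(rows)


def select_markers_wilcoxon(
    matrix: ExpressionMatrix,
    labels,
    n_top: int = 100,
    p_adj_max: float = 0.05,
    min_log2fc: float = 0.0,
) -> tuple[dict[str, GeneSignature], dict[str, pd.DataFrame]]:
    """Per-class marker signatures by rank-sum (Wilcoxon/Mann–Whitney) test.

    For each class, every gene is tested class-vs-rest (two-sided, averaged
    ties), p-values are Benjamini–Hochberg adjusted, genes are filtered by
    adjusted p < ``p_adj_max`` and log2FC > ``min_log2fc`` (fold change of
    expm1-scale means with a 1e-9 pseudocount) and the top ``n_top`` by
    ascending adjusted p (ties: descending log2FC) form the signature, most
    significant first. Classes with fewer than 3 cells are skipped.
    """
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != matrix.n_cells:
        raise ValidationError("labels length does not match number of cells")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("need at least two classes for marker selection")
    X = matrix.dense()
    e = np.expm1(X)
    signatures: dict[str, GeneSignature] = {}
    stats: dict[str, pd.DataFrame] = {}
    for cls in classes:
        mask = labels == cls
        if mask.sum() < 3:
            logger.warning("class %r has %d cells (<3); skipped", cls, int(mask.sum()))
            continue
        res = mannwhitneyu(X[mask], X[~mask], axis=0, alternative="two-sided",
                           method="asymptotic")
        pvals = np.asarray(res.pvalue, dtype=float)
        u = np.asarray(res.statistic, dtype=float)
        p_adj = false_discovery_control(pvals, method="bh")
        log2fc = np.log2((e[mask].mean(axis=0) + 1e-9) / (e[~mask].mean(axis=0) + 1e-9))
        df = pd.DataFrame({
            "gene": matrix.gene_ids, "u": u, "p": pvals, "p_adj": p_adj, "log2fc": log2fc,
        })
        stats[cls] = df
        hits = df[(df["p_adj"] < p_adj_max) & (df["log2fc"] > min_log2fc)]
        hits = hits.sort_values(["p_adj", "log2fc"], ascending=[True, False],
                                kind="stable").head(n_top)
        if hits.empty:
            logger.warning("class %r has no significant markers; skipped", cls)
            continue
        signatures[cls] = GeneSignature(name=cls, genes=list(hits["gene"]))
    return signatures, stats


def save_benchmark(df: pd.DataFrame, summary: dict, out_prefix) -> None:
    """Write a benchmark's tidy table (`<prefix>.tsv`, one row per
    condition × run) and its JSON summary (`<prefix>.json`)."""
    import json
    from pathlib import Path

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2, default=float) + "\n")


def select_noise_pool(
    stats: pd.DataFrame,
    p_adj_min: float = 0.01,
    max_abs_log2fc: float = 0.5,
) -> list[str]:
    """Genes with no discriminative signal, usable as a noise pool: adjusted
    p > ``p_adj_min`` and |log2FC| ≤ ``max_abs_log2fc``."""
    sel = stats[(stats["p_adj"] > p_adj_min) & (stats["log2fc"].abs() <= max_abs_log2fc)]
    return list(sel["gene"])
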