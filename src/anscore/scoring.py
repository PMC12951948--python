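"""Gene-signature scoring methods.

Two families are implemented:

* the Tirosh family (ANS, bin-sampled controls as in Seurat/scanpy, all-genes
  controls, least-variable controls), where a cell's score is the mean over
  signature genes of (expression − mean control expression):

      score_j = (1/m) Σ_{s∈S} ( X_{j,s} − (1/|C_s|) Σ_{k∈C_s} X_{j,k} )

* rank-based methods (UCell, JASMINE) that only use within-cell gene ranks
  and are therefore insensitive to cell-wise monotone distortions but blind
  to absolute expression levels.

``METHODS`` lists the public method names accepted by :func:`score_all` and
the command line: ``ans``, ``seurat``, ``scanpy_bins``, ``seurat_ag``,
``seurat_lvg``, ``ucell``, ``jasmine_lh``, ``jasmine_or``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from . import controls as ctrl
from .core import (
    ControlAssignment,
    ControlConfig,
    ExpressionMatrix,
    GeneSignature,
    MeanExpressionProfile,
    ScoreMatrix,
    ValidationError,
    intersect_signature,
)

logger = logging.getLogger(__name__)

METHODS = (
    "ans",
    "seurat",
    "scanpy_bins",
    "seurat_ag",
    "seurat_lvg",
    "ucell",
    "jasmine_lh",
    "jasmine_or",
)

#: control strategy behind each Tirosh-family method name
TIROSH_METHODS = {
    "ans": ("ans", False),
    "seurat": ("bin_sampled", False),
    "scanpy_bins": ("bin_sampled", True),
    "seurat_ag": ("bin_all_genes", False),
    "seurat_lvg": ("bin_least_variable", False),
}


def score_tirosh(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    controls: ControlAssignment,
) -> np.ndarray:
    """Evaluate the Tirosh score for every cell given a control assignment.

    m in the averaging is the number of *retained* signature genes.
    """
    genes = controls.retained_signature_genes
    if not genes:
        raise ValidationError("no retained signature genes to score")
    n = matrix.n_cells
    acc = np.zeros(n, dtype=float)
    sig_idx = matrix.gene_indices(genes)
    sig_cols = matrix.columns(sig_idx)
    for col, g in enumerate(genes):
        cidx = matrix.gene_indices(controls.mapping[g])
        ctrl_mean = matrix.columns(cidx).mean(axis=1)
        acc += sig_cols[:, col] - ctrl_mean
    return acc / len(genes)


def score_ans(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig | None = None,
    profile: MeanExpressionProfile | None = None,
) -> tuple[np.ndarray, ControlAssignment]:
    """Adjusted Neighborhood Scoring: top-expression exclusion, neighborhood
    control selection, then the Tirosh score. Returns the per-cell scores and
    the full control assignment (provenance, incl. the exclusion report)."""
    config = config or ControlConfig(strategy="ans")
    assignment = ctrl.controls_ans(matrix, sig, config, profile)
    scores = score_tirosh(matrix, sig, assignment)
    return scores, assignment


def score_ucell(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    max_rank: int = 1500,
) -> np.ndarray:
    """UCell: a per-cell Mann–Whitney U statistic on gene ranks.

    Within each cell all p genes are ranked by decreasing expression with
    averaged ties; ranks beyond ``max_rank`` are clamped to ``max_rank + 1``.
    With r_s the (clamped) rank of signature gene s,

        U = Σ_s r_s − m(m+1)/2,      score = 1 − U / (m · max_rank)

    Scores lie in [0, 1] and depend only on the cell's own ranks, so removing
    or adding other cells never changes a cell's score.
    """
    m = len(sig.genes)
    if m > max_rank:
        raise ValidationError(f"signature size {m} exceeds max_rank {max_rank}")
    sig_idx = matrix.gene_indices(sig.genes)
    X = matrix.dense()
    ranks = rankdata(-X, axis=1, method="average")
    r = ranks[:, sig_idx]
    r = np.minimum(r, max_rank + 1)
    u = r.sum(axis=1) - m * (m + 1) / 2.0
    return 1.0 - u / (m * max_rank)


def _minmax(v: np.ndarray, what: str) -> np.ndarray:
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        logger.warning("JASMINE %s component has zero range; normalized to zeros", what)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def score_jasmine(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    mode: str = "likelihood",
) -> np.ndarray:
    """JASMINE: mean rank of expressed signature genes combined with a
    per-cell enrichment value (odds ratio or likelihood).

    For cell j let *expressed* mean nonzero. The rank component is the mean
    rank (ascending by expression, averaged ties) of the expressed signature
    genes among all expressed genes, divided by the number of expressed
    genes; 0 when no signature gene is expressed. The enrichment component
    comes from the 2×2 table (a = expressed signature genes, b = unexpressed
    signature genes, g = expressed non-signature, h = unexpressed
    non-signature): OR = a·h/(b·g), likelihood = a·(g+h)/(g·(a+b)). Cells
    whose enrichment denominator is zero while a > 0 receive the maximum
    enrichment observed among well-defined cells, or 1 if that maximum is not
    positive (maximal-enrichment guard, keeps scores finite and monotone in
    a); cells with a = 0 receive 0. Both components are min–max normalized across
    all cells and averaged.
    """
    if mode not in ("likelihood", "odds_ratio"):
        raise ValidationError(f"unknown JASMINE mode {mode!r}")
    if matrix.n_cells < 2:
        raise ValidationError("JASMINE needs at least 2 cells (min–max normalization)")
    X = matrix.dense()
    n, p = X.shape
    sig_idx = matrix.gene_indices(sig.genes)
    in_sig = np.zeros(p, dtype=bool)
    in_sig[sig_idx] = True
    m = len(sig.genes)

    rm = np.zeros(n)
    enrich = np.full(n, np.nan)
    guard_triggered = 0
    for j in range(n):
        expressed = X[j] > 0
        ne = int(expressed.sum())
        a = int((expressed & in_sig).sum())
        b = m - a
        g = ne - a
        h = (p - ne) - b
        if a > 0:
            vals = X[j, expressed]
            ranks = rankdata(vals, method="average")  # ascending by expression
            rm[j] = ranks[in_sig[expressed]].mean() / ne
        if a == 0:
            enrich[j] = 0.0
        elif mode == "odds_ratio":
            enrich[j] = (a * h) / (b * g) if b * g != 0 else np.nan
        else:
            enrich[j] = (a * (g + h)) / (g * (a + b)) if g != 0 else np.nan

    undefined = np.isnan(enrich)
    if undefined.any():
        guard_triggered = int(undefined.sum())
        defined = enrich[~undefined]
        fill = float(defined.max()) if defined.size else 0.0
        if fill <= 0.0:
            fill = 1.0  # keep maximal-enrichment cells above every a=0 cell
        enrich[undefined] = fill
        logger.warning(
            "JASMINE enrichment undefined for %d cell(s); assigned running maximum %g",
            guard_triggered, fill,
        )
    return (_minmax(rm, "rank") + _minmax(enrich, "enrichment")) / 2.0


# ---------------------------------------------------------------------------
# Multi-signature front-end
# ---------------------------------------------------------------------------

def drop_overlapping_genes(signatures: list[GeneSignature]) -> list[GeneSignature]:
    """Remove genes that appear in more than one signature (shared genes can
    bias scoring across cell types); raises if a signature empties out."""
    from collections import Counter

    counts = Counter(g for s in signatures for g in s.genes)
    shared = {g for g, k in counts.items() if k > 1}
    if shared:
        logger.warning("dropping %d gene(s) shared between signatures", len(shared))
    out = []
    for s in signatures:
        genes = [g for g in s.genes if g not in shared]
        if not genes:
            raise ValidationError(
                f"signature {s.name!r} has no genes left after removing overlaps"
            )
        out.append(GeneSignature(name=s.name, genes=genes))
    return out


def score_signature(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    method: str,
    config: ControlConfig | None = None,
    max_rank: int = 1500,
    profile: MeanExpressionProfile | None = None,
) -> tuple[np.ndarray, ControlAssignment | None]:
    """Score one signature with one method; returns (scores, provenance)."""
    if method not in METHODS:
        raise ValidationError(f"unknown scoring method {method!r}; expected one of {METHODS}")
    sig, _ = intersect_signature(sig, matrix)
    if method in TIROSH_METHODS:
        strategy, pooled = TIROSH_METHODS[method]
        cfg = config or ControlConfig()
        cfg = ControlConfig(
            control_size=cfg.control_size,
            n_bins=cfg.n_bins,
            strategy=strategy,
            random_seed=cfg.random_seed,
            pooled=pooled or cfg.pooled,
            use_normalized_dispersion=cfg.use_normalized_dispersion,
        )
        assignment = ctrl.build_controls(matrix, sig, cfg, profile)
        return score_tirosh(matrix, sig, assignment), assignment
    if method == "ucell":
        return score_ucell(matrix, sig, max_rank=max_rank), None
    if method == "jasmine_lh":
        return score_jasmine(matrix, sig, mode="likelihood"), None
    return score_jasmine(matrix, sig, mode="odds_ratio"), None


def score_all(
    matrix: ExpressionMatrix,
    signatures: list[GeneSignature],
    method: str,
    config: ControlConfig | None = None,
    max_rank: int = 1500,
    drop_overlap: bool = False,
) -> ScoreMatrix:
    """Score every signature with the same method on the same matrix.

    All signatures are scored on all cells simultaneously (joint scoring, the
    recommended mode); per-signature errors are collected and reported
    together.
    """
    if not signatures:
        raise ValidationError("need at least one signature")
    if drop_overlap:
        signatures = drop_overlapping_genes(signatures)
    profile = ctrl.mean_expression(matrix) if method in TIROSH_METHODS else None
    cols, names, errors = [], [], []
    provenance: dict = {
        "method": method,
        "max_rank": max_rank if method == "ucell" else None,
        "control_config": None,
        "assignments": {},
    }
    if method in TIROSH_METHODS:
        cfg = config or ControlConfig()
        provenance["control_config"] = {
            "control_size": cfg.control_size,
            "n_bins": cfg.n_bins,
            "random_seed": cfg.random_seed,
        }
    for sig in signatures:
        try:
            scores, assignment = score_signature(
                matrix, sig, method, config=config, max_rank=max_rank, profile=profile
            )
        except ValidationError as err:
            errors.append(f"{sig.name}: {err}")
            continue
        cols.append(scores)
        names.append(sig.name)
        if assignment is not None:
            provenance["assignments"][sig.name] = {
                "retained": list(assignment.retained_signature_genes),
                "excluded": list(assignment.excluded_signature_genes),
                "strategy": assignment.strategy,
            }
    if errors:
        raise ValidationError("scoring failed for signature(s): " + "; ".join(errors))
    return ScoreMatrix(
        values=np.column_stack(cols),
        cell_ids=list(matrix.cell_ids),
        signature_names=names,
        method=method,
        provenance=provenance,
    )
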