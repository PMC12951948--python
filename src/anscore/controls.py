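"""Control-gene selection strategies for Tirosh-style signature scoring.

Tirosh-style scores subtract, from each signature gene's expression, the mean
of a set of *control genes* with matched average expression; this normalizes
cell-intrinsic technical effects (capture depth, complexity). This module
implements four ways of building the control sets:

``bin_sampled``
    Classic approach: genes are ranked by average expression and split into
    ``n_bins`` equally sized expression bins; each signature gene receives c
    genes sampled uniformly from its bin.
``bin_all_genes``
    Every non-signature gene of the bin is a control (c is ignored).
``bin_least_variable``
    The c genes of the bin with the smallest dispersion.
``ans`` (Adjusted Neighborhood Scoring)
    The contiguous window of c non-signature genes whose mean average
    expression best matches the signature gene's average expression; signature
    genes ranked in the top ⌊c/2⌋ of average expression are excluded because
    no valid (centered) neighborhood exists for them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import (
    ControlAssignment,
    ControlConfig,
    ExpressionMatrix,
    GeneSignature,
    MeanExpressionProfile,
    ValidationError,
)

logger = logging.getLogger(__name__)

EXCLUDED_TOP_EXPRESSED = "top_expressed"

__all__ = [
    "mean_expression",
    "bin_genes",
    "bin_sizes",
    "seurat_dispersion",
    "controls_bin_sampled",
    "controls_all_genes",
    "controls_least_variable",
    "exclude_top_expressed",
    "controls_ans",
    "build_controls",
]


def mean_expression(
    matrix: ExpressionMatrix, exclude: list[str] | None = None
) -> MeanExpressionProfile:
    """Per-gene mean over all cells, sorted nondecreasing with stable ties.

    ``exclude`` removes genes (e.g. the signature) before sorting, producing
    the signature-excluded profile used by the neighborhood search.
    """
    means = matrix.gene_means()
    gene_ids = matrix.gene_ids
    if exclude:
        excl = set(exclude)
        unknown = excl - set(gene_ids)
        if unknown:
            raise ValidationError(f"excluded genes not in matrix: {sorted(unknown)[:5]}")
        keep = [i for i, g in enumerate(gene_ids) if g not in excl]
        means = means[keep]
        gene_ids = [gene_ids[i] for i in keep]
    order = np.argsort(means, kind="stable")
    return MeanExpressionProfile(
        gene_ids=[gene_ids[i] for i in order], means=means[order]
    )


def bin_sizes(p: int, n_bins: int) -> list[int]:
    """Sizes of the n_bins contiguous rank bins over p genes.

    Sizes differ by at most one; when p is not divisible by n_bins the extra
    genes go to the lowest-expression bins (fixed, documented convention).
    """
    base, rem = divmod(p, n_bins)
    return [base + 1] * rem + [base] * (n_bins - rem)


def bin_genes(profile: MeanExpressionProfile, n_bins: int) -> dict[str, int]:
    """Partition the sorted profile into expression bins; gene → bin index.

    Bin indices run 0..n_bins-1 in increasing expression.
    """
    p = len(profile)
    if n_bins > p:
        raise ValidationError(f"n_bins={n_bins} exceeds number of genes ({p})")
    out: dict[str, int] = {}
    start = 0
    for b, size in enumerate(bin_sizes(p, n_bins)):
        for g in profile.gene_ids[start : start + size]:
            out[g] = b
        start += size
    return out


def _bins_as_lists(profile: MeanExpressionProfile, n_bins: int) -> list[list[str]]:
    lists: list[list[str]] = []
    start = 0
    for size in bin_sizes(len(profile), n_bins):
        lists.append(list(profile.gene_ids[start : start + size]))
        start += size
    return lists


def seurat_dispersion(
    matrix: ExpressionMatrix, normalized: bool = True, n_mean_bins: int = 20
) -> pd.Series:
    """Per-gene dispersion statistic of the "seurat" highly-variable-genes flavor.

    The log-expression values are expm1-transformed back to the normalized
    scale; dispersion is variance/mean per gene. With ``normalized=True`` the
    log-dispersions are z-scored within ``n_mean_bins`` bins of log1p mean
    expression (the standard normalized dispersion); with ``normalized=False``
    the raw variance/mean ratio is returned (sensitivity-check variant).

    Zero-variance genes get dispersion ``-inf`` in the normalized variant so
    that "least variable" rankings always place them first.
    """
    X = matrix.dense()
    e = np.expm1(X)
    mean = e.mean(axis=0)
    var = e.var(axis=0, ddof=1) if matrix.n_cells > 1 else np.zeros(matrix.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = var / np.where(mean == 0, np.nan, mean)
    raw = np.where(mean == 0, 0.0, raw)  # all-zero gene: no variability
    if not normalized:
        return pd.Series(raw, index=matrix.gene_ids, name="dispersion")

    zerovar = raw <= 1e-12  # numerically constant gene: always least variable
    with np.errstate(divide="ignore"):
        logdisp = np.log(np.where(raw > 1e-12, raw, np.nan))
    logmean = np.log1p(mean)
    df = pd.DataFrame({"mean": logmean, "disp": logdisp})
    df["bin"] = pd.cut(df["mean"], bins=min(n_mean_bins, max(1, matrix.n_genes)))
    grouped = df.groupby("bin", observed=True)["disp"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std")
    # single-gene bins: z-score degenerates to dispersion/itself = 1
    single = sd.isna()
    sd = sd.where(~single, mu).replace(0.0, np.nan).fillna(1.0)
    mu = mu.where(~single, 0.0)
    z = ((df["disp"] - mu) / sd).to_numpy()
    z[zerovar] = -np.inf
    z[np.isnan(z)] = np.inf  # undefined dispersion ranks last
    return pd.Series(z, index=matrix.gene_ids, name="dispersion_norm")


# ---------------------------------------------------------------------------
# Bin-based strategies
# ---------------------------------------------------------------------------

def _prepare_bins(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig,
    profile: MeanExpressionProfile | None,
):
    if profile is None:
        profile = mean_expression(matrix)
    bins = _bins_as_lists(profile, config.n_bins)
    gene_bin = {}
    for b, genes in enumerate(bins):
        for g in genes:
            gene_bin[g] = b
    sig_set = set(sig.genes)
    return profile, bins, gene_bin, sig_set


def controls_bin_sampled(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig,
    profile: MeanExpressionProfile | None = None,
) -> ControlAssignment:
    """c controls sampled uniformly without replacement from each signature
    gene's expression bin (non-signature genes only).

    With ``config.pooled=True`` the eligible genes of *all* touched bins are
    pooled and a single control set of size c is sampled and shared by the
    whole signature. Deterministic given ``config.random_seed``.
    """
    _, bins, gene_bin, sig_set = _prepare_bins(matrix, sig, config, profile)
    rng = np.random.default_rng(config.random_seed)
    c = config.control_size
    mapping: dict[str, list[str]] = {}

    if config.pooled:
        touched = sorted({gene_bin[g] for g in sig.genes})
        pool = [g for b in touched for g in bins[b] if g not in sig_set]
        if not pool:
            raise ValidationError("no eligible control genes in the signature's bins")
        if len(pool) <= c:
            if len(pool) < c:
                logger.warning(
                    "pooled bins hold %d eligible genes < control_size %d; using all",
                    len(pool), c,
                )
            chosen = list(pool)
        else:
            chosen = [pool[i] for i in rng.choice(len(pool), size=c, replace=False)]
        for g in sig.genes:
            mapping[g] = list(chosen)
    else:
        warned_bins: set[int] = set()
        for g in sig.genes:
            b = gene_bin[g]
            eligible = [x for x in bins[b] if x not in sig_set]
            if not eligible:
                raise ValidationError(f"no eligible control genes in bin of {g!r}")
            if len(eligible) <= c:
                if len(eligible) < c and b not in warned_bins:
                    warned_bins.add(b)
                    logger.warning(
                        "bin %d holds %d eligible genes < control_size %d; using all",
                        b, len(eligible), c,
                    )
                mapping[g] = list(eligible)
            else:
                idx = rng.choice(len(eligible), size=c, replace=False)
                mapping[g] = [eligible[i] for i in idx]

    return ControlAssignment(
        mapping=mapping,
        retained_signature_genes=list(sig.genes),
        strategy="bin_sampled",
    )


def controls_all_genes(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig,
    profile: MeanExpressionProfile | None = None,
) -> ControlAssignment:
    """All non-signature genes of each signature gene's bin; c is ignored."""
    _, bins, gene_bin, sig_set = _prepare_bins(matrix, sig, config, profile)
    mapping: dict[str, list[str]] = {}
    for g in sig.genes:
        eligible = [x for x in bins[gene_bin[g]] if x not in sig_set]
        if not eligible:
            raise ValidationError(f"bin of {g!r} is empty after removing signature genes")
        mapping[g] = eligible
    return ControlAssignment(
        mapping=mapping,
        retained_signature_genes=list(sig.genes),
        strategy="bin_all_genes",
    )


def controls_least_variable(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig,
    profile: MeanExpressionProfile | None = None,
) -> ControlAssignment:
    """The c non-signature genes of each bin with smallest dispersion.

    Dispersion is the seurat-flavor normalized dispersion by default
    (``config.use_normalized_dispersion=False`` switches to raw
    variance/mean). Fully deterministic: ties keep bin (expression) order.
    """
    _, bins, gene_bin, sig_set = _prepare_bins(matrix, sig, config, profile)
    disp = seurat_dispersion(matrix, normalized=config.use_normalized_dispersion)
    c = config.control_size
    mapping: dict[str, list[str]] = {}
    per_bin_cache: dict[int, list[str]] = {}
    for g in sig.genes:
        b = gene_bin[g]
        if b not in per_bin_cache:
            eligible = [x for x in bins[b] if x not in sig_set]
            if not eligible:
                raise ValidationError(f"bin of {g!r} is empty after removing signature genes")
            vals = disp.loc[eligible].to_numpy()
            order = np.argsort(vals, kind="stable")
            per_bin_cache[b] = [eligible[i] for i in order]
            if len(eligible) < c:
                logger.warning(
                    "bin %d holds %d eligible genes < control_size %d; using all",
                    b, len(eligible), c,
                )
        mapping[g] = per_bin_cache[b][:c]
    return ControlAssignment(
        mapping=mapping,
        retained_signature_genes=list(sig.genes),
        strategy="bin_least_variable",
    )


# ---------------------------------------------------------------------------
# ANS
# ---------------------------------------------------------------------------

def exclude_top_expressed(
    sig: GeneSignature,
    matrix: ExpressionMatrix,
    config: ControlConfig,
    profile: MeanExpressionProfile | None = None,
) -> tuple[GeneSignature, list[tuple[str, str]]]:
    """Drop signature genes ranked in the top ⌊c/2⌋ of average expression.

    For such genes a size-c neighborhood of expression-matched controls cannot
    be centered on the gene; scoring them would systematically understate
    their scores. Ranking is over the all-genes mean profile (stable ties).
    Raises if every signature gene falls in the exclusion zone.
    """
    if profile is None:
        profile = mean_expression(matrix)
    n_excl = config.control_size // 2
    forbidden = set(profile.gene_ids[len(profile) - n_excl :]) if n_excl else set()
    retained = [g for g in sig.genes if g not in forbidden]
    excluded = [(g, EXCLUDED_TOP_EXPRESSED) for g in sig.genes if g in forbidden]
    if not retained:
        raise ValidationError(
            f"all genes of signature {sig.name!r} lie within the top "
            f"{n_excl} expressed genes; adjust the size of either the "
            "signature or the control sets"
        )
    if excluded:
        logger.warning(
            "signature %r: excluded %d gene(s) in the top %d expressed genes: %s",
            sig.name, len(excluded), n_excl, [g for g, _ in excluded][:10],
        )
    return GeneSignature(name=sig.name, genes=retained), excluded


def controls_ans(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig,
    profile: MeanExpressionProfile | None = None,
) -> ControlAssignment:
    """Adjusted Neighborhood Scoring control selection.

    Let g̃ be the nondecreasing mean-expression profile of the non-signature
    genes. Each retained signature gene s receives the contiguous window of c
    genes of g̃ whose mean is closest to s's average expression ḡ_s,
    C_s = argmin over windows |ḡ_s − windowMean|; ties are broken toward the
    lower-expression window (leftmost index). Signature genes in the top
    ⌊c/2⌋ expressed genes are excluded beforehand.
    """
    if profile is None:
        profile = mean_expression(matrix)
    c = config.control_size
    retained, excluded = exclude_top_expressed(sig, matrix, config, profile)

    sig_set = set(sig.genes)
    keep = [i for i, g in enumerate(profile.gene_ids) if g not in sig_set]
    tilde_genes = [profile.gene_ids[i] for i in keep]
    tilde_means = profile.means[keep]
    n_windows = len(tilde_genes) - c + 1
    if n_windows < 1:
        raise ValidationError(
            f"control size {c} exceeds available non-signature genes ({len(tilde_genes)})"
        )

    # window means of the sorted profile are nondecreasing; argmin of the
    # absolute distance returns the leftmost minimizer by construction
    csum = np.concatenate([[0.0], np.cumsum(tilde_means)])
    wmeans = (csum[c:] - csum[:-c]) / c

    gene_mean = dict(zip(profile.gene_ids, profile.means))
    mapping: dict[str, list[str]] = {}
    for g in retained.genes:
        k = int(np.argmin(np.abs(gene_mean[g] - wmeans)))
        mapping[g] = tilde_genes[k : k + c]

    return ControlAssignment(
        mapping=mapping,
        retained_signature_genes=list(retained.genes),
        excluded_signature_genes=excluded,
        strategy="ans",
    )


_STRATEGY_FUNCS = {
    "ans": controls_ans,
    "bin_sampled": controls_bin_sampled,
    "bin_all_genes": controls_all_genes,
    "bin_least_variable": controls_least_variable,
}


def build_controls(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    config: ControlConfig,
    profile: MeanExpressionProfile | None = None,
) -> ControlAssignment:
    """Dispatch to the strategy named in ``config.strategy``."""
    return _STRATEGY_FUNCS[config.strategy](matrix, sig, config, profile)
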