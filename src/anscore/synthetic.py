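"""Synthetic scRNA-seq expression data with known ground truth.

The generator emulates the structural features of real log-normalized
single-cell matrices that signature scoring is sensitive to, without
attempting full count-level realism:

* a long-tailed per-gene mean expression distribution (log-normal baseline),
  which is what makes the top expression bin wide and control selection hard
  for highly expressed genes;
* cell types defined by disjoint (or deliberately overlapping) marker sets
  upregulated by a configurable log2 fold-change;
* dropout as stochastic zeroing — independent Bernoulli by default, or
  mean-dependent (low-expression genes drop out more) as an option;
* sample/batch structure in which batches differ by a chemistry-like
  capture-efficiency shift: the batch ``depth_factor`` acts per gene with a
  random exponent, so it survives library-size normalization the way real
  chemistry differences do (a uniform per-cell factor would be normalized
  away exactly).

Cells are drawn as baseline × type-effect × batch-efficiency × log-normal
noise, zeroed by dropout, library-size normalized to the median depth, and
log1p-transformed. Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneSignature, ValidationError, validate_matrix

__all__ = [
    "SampleSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_homogeneous",
    "high_sparsity_config",
    "sparsity",
]


@dataclass(frozen=True)
class SampleSpec:
    """One sample: its batch membership and per-type cell counts."""

    name: str
    batch: str
    cell_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator.

    ``cell_types`` declares the types and their default cell counts; when
    ``samples`` is given, counts come from the per-sample ``cell_counts``
    instead and ``batch_depth_factors`` maps each batch name to its
    capture-efficiency factor (1.0 = no batch effect).
    """

    n_genes: int = 2000
    cell_types: tuple = (("typeA", 500), ("typeB", 500), ("typeC", 500))
    markers_per_type: int = 20
    marker_log2fc: float = 2.0
    marker_overlap: int = 0  # markers shared between consecutive types
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.3
    mean_dependent_dropout: bool = False
    samples: tuple = ()
    batch_depth_factors: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ValidationError("noise_sd and baseline_log_sd must be >= 0")
        if self.markers_per_type < 0 or self.marker_overlap < 0:
            raise ValidationError("marker counts must be >= 0")
        if self.marker_overlap >= self.markers_per_type and self.markers_per_type > 0:
            raise ValidationError("marker_overlap must be smaller than markers_per_type")
        n_types = len(self.cell_types)
        need = self.markers_per_type * n_types - self.marker_overlap * max(0, n_types - 1)
        if need > self.n_genes:
            raise ValidationError(
                f"{need} marker genes required but only {self.n_genes} genes configured"
            )
        for spec in self.samples:
            unknown = set(spec.cell_counts) - {t for t, _ in self.cell_types}
            if unknown:
                raise ValidationError(f"sample {spec.name!r} references unknown types {unknown}")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    labels: pd.Series  # truth cell-type label per cell
    signatures: dict[str, GeneSignature]  # marker signature per type
    config: SyntheticConfig


def _marker_blocks(config: SyntheticConfig) -> dict[str, list[int]]:
    """Contiguous (optionally overlapping) marker gene index blocks per type."""
    blocks: dict[str, list[int]] = {}
    step = config.markers_per_type - config.marker_overlap
    for t, (name, _) in enumerate(config.cell_types):
        start = t * step
        blocks[name] = list(range(start, start + config.markers_per_type))
    return blocks


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a log1p-normalized matrix with truth labels and marker sets.

    Marker genes of type t have pre-noise expression elevated by
    ``2**marker_log2fc`` in type-t cells. Bit-identical for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_genes
    type_names = [name for name, _ in config.cell_types]

    # cell bookkeeping: (type, sample, batch) per cell
    rows: list[tuple[str, str, str]] = []
    if config.samples:
        factors = config.batch_depth_factors or {}
        for spec in config.samples:
            for tname, k in spec.cell_counts.items():
                rows += [(tname, spec.name, spec.batch)] * int(k)
    else:
        factors = {}
        for tname, k in config.cell_types:
            rows += [(tname, "sample_0", "batch_0")] * int(k)
    if not rows:
        raise ValidationError("configuration produces zero cells")
    n = len(rows)
    labels = np.array([r[0] for r in rows])
    samples = np.array([r[1] for r in rows])
    batches = np.array([r[2] for r in rows])

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=p)
    markers = _marker_blocks(config) if config.markers_per_type else {t: [] for t in type_names}

    # chemistry-like batch effect: per-gene efficiency depth_factor ** u_g
    u = rng.uniform(0.0, 1.0, size=p)
    batch_eff = {}
    for b in np.unique(batches):
        f = float(factors.get(b, 1.0))
        batch_eff[b] = np.power(f, u) if f != 1.0 else np.ones(p)

    fc = 2.0 ** config.marker_log2fc
    mu = np.empty((n, p), dtype=float)
    for j in range(n):
        m = baseline.copy()
        idx = markers.get(labels[j], [])
        if idx:
            m[idx] = m[idx] * fc
        mu[j] = m * batch_eff[batches[j]]

    if config.noise_sd > 0:
        expr = mu * rng.lognormal(0.0, config.noise_sd, size=(n, p))
    else:
        expr = mu.copy()

    if config.dropout_rate > 0:
        if config.mean_dependent_dropout:
            # logistic in log-mean: low-expression genes drop out more; the
            # threshold is the dropout_rate quantile of the baseline so the
            # overall zero fraction stays near dropout_rate
            from scipy.special import expit

            x0 = np.quantile(np.log(baseline), config.dropout_rate)
            pdrop = expit(x0 - np.log(mu))
        else:
            pdrop = np.full((n, p), config.dropout_rate)
        expr[rng.random((n, p)) < pdrop] = 0.0

    lib = expr.sum(axis=1)
    if np.any(lib == 0):
        raise ValidationError("a cell lost all counts to dropout; lower dropout_rate")
    target = float(np.median(lib))
    X = np.log1p(expr / lib[:, None] * target)

    gene_ids = [f"g{i:04d}" for i in range(p)]
    cell_ids = [f"c{j:05d}" for j in range(n)]
    meta = pd.DataFrame({"sample_id": samples, "batch_id": batches, "label": labels})
    matrix = validate_matrix(
        ExpressionMatrix(values=X, cell_ids=cell_ids, gene_ids=gene_ids, cell_metadata=meta)
    )
    signatures = {
        t: GeneSignature(name=t, genes=[gene_ids[i] for i in markers[t]])
        for t in type_names
        if markers[t]
    }
    return SyntheticDataset(
        matrix=matrix,
        labels=pd.Series(labels, index=cell_ids, name="label"),
        signatures=signatures,
        config=config,
    )


def generate_homogeneous(config: SyntheticConfig) -> ExpressionMatrix:
    """Single-cell-type i.i.d. data from the baseline model (no markers).

    The fixture for control-bias scans, where any systematic deviation of a
    single-gene score from zero is selection bias, not biology.
    """
    if len(config.cell_types) != 1:
        raise ValidationError("generate_homogeneous requires exactly one cell type")
    from dataclasses import replace

    cfg = replace(config, markers_per_type=0, marker_overlap=0)
    return generate_dataset(cfg).matrix


def high_sparsity_config(n_cells: int = 500, n_genes: int = 2000, seed: int = 0) -> SyntheticConfig:
    """Named preset reproducing ~90% zeros, the hardest regime of real data."""
    return SyntheticConfig(
        n_genes=n_genes,
        cell_types=(("typeA", n_cells // 2), ("typeB", n_cells - n_cells // 2)),
        markers_per_type=20,
        marker_log2fc=2.0,
        dropout_rate=0.9,
        seed=seed,
    )


def sparsity(matrix: ExpressionMatrix) -> float:
    """Fraction of zero entries."""
    if matrix.is_sparse:
        return 1.0 - matrix.values.nnz / (matrix.n_cells * matrix.n_genes)
    return float(np.mean(np.asarray(matrix.values) == 0))
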