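"""Shared data types and indexing conventions.

All matrices are oriented cells-as-rows, genes-as-columns. Gene and cell
identifiers are case-sensitive opaque strings; no symbol aliasing or
versioned-ID stripping is performed — signature genes are matched to matrix
genes verbatim. Sparse (CSR/CSC) and dense storage are interchangeable: every
operation in this package yields the same result for both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_STRATEGIES = ("ans", "bin_sampled", "bin_all_genes", "bin_least_variable")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """A preprocessed (log-transformed, normalized) cells × genes matrix X.

    Parameters
    ----------
    values
        Non-negative finite matrix of shape (n_cells, n_genes); dense
        ``numpy.ndarray`` or any ``scipy.sparse`` matrix.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    cell_metadata
        Optional per-cell table (e.g. ``sample_id``, ``batch_id``, ``label``),
        indexed like ``cell_ids``.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_metadata: pd.DataFrame | None = None

    _gene_index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Column indices for ``genes``; raises KeyError on unknown genes."""
        return np.asarray([self._gene_index[g] for g in genes], dtype=np.intp)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    # -- numeric helpers shared by every module ---------------------------
    def dense(self) -> np.ndarray:
        """Dense float view/copy of the values (sparse inputs are expanded)."""
        if self.is_sparse:
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def columns(self, idx: np.ndarray) -> np.ndarray:
        """Dense (n_cells, len(idx)) block of the requested gene columns."""
        if self.is_sparse:
            return np.asarray(self.values.tocsc()[:, idx].todense(), dtype=float)
        return np.asarray(self.values[:, idx], dtype=float)

    def gene_means(self) -> np.ndarray:
        """Per-gene arithmetic mean over all cells, in gene_ids order."""
        if self.is_sparse:
            return np.asarray(self.values.mean(axis=0)).ravel()
        return np.asarray(self.values, dtype=float).mean(axis=0)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the cells selected by a boolean mask or
        integer index array; metadata rows follow."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        vals = self.values[idx, :] if not self.is_sparse else self.values.tocsr()[idx, :]
        meta = None
        if self.cell_metadata is not None:
            meta = self.cell_metadata.iloc[idx].reset_index(drop=True)
        return ExpressionMatrix(
            values=vals,
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            cell_metadata=meta,
        )


@dataclass
class GeneSignature:
    """A named ordered gene set S of size m.

    Order is meaningful when the signature was produced by marker selection
    (most significant first); scoring itself is order-invariant.
    """

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValidationError(f"signature {self.name!r} contains duplicate gene {dup!r}")
        if len(self.genes) < 1:
            raise ValidationError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MeanExpressionProfile:
    """Genes sorted by nondecreasing mean expression across cells.

    Ties keep original gene order (stable sort), which makes every downstream
    bin/window selection deterministic.
    """

    gene_ids: list[str]
    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if len(self.gene_ids) != self.means.shape[0]:
            raise ValidationError("profile gene_ids and means length mismatch")
        if self.means.size > 1 and np.any(np.diff(self.means) < 0):
            raise ValidationError("mean expression profile is not nondecreasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ControlConfig:
    """Parameters of control-gene selection.

    ``control_size`` is c, the number of control genes per signature gene
    (ignored by the all-genes strategy); ``n_bins`` the number of equally
    sized expression bins used by the bin-based strategies.
    """

    control_size: int = 100
    n_bins: int = 25
    strategy: str = "ans"
    random_seed: int | None = None
    pooled: bool = False  # bin_sampled: one control set shared by the signature
    use_normalized_dispersion: bool = True  # bin_least_variable ranking statistic

    def __post_init__(self) -> None:
        if self.control_size < 1:
            raise ValidationError("control_size must be >= 1")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if self.strategy not in VALID_STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; expected one of {VALID_STRATEGIES}"
            )


@dataclass
class ControlAssignment:
    """Per-signature-gene control sets C_s.

    ``mapping`` maps every retained signature gene to its control genes (in a
    deterministic order); control sets never contain signature genes.
    ``excluded_signature_genes`` lists (gene, reason) pairs for signature genes
    that could not be scored (e.g. inside the top-expression exclusion zone).
    """

    mapping: dict[str, list[str]]
    retained_signature_genes: list[str]
    excluded_signature_genes: list[tuple[str, str]] = field(default_factory=list)
    strategy: str = ""

    def __post_init__(self) -> None:
        missing = [g for g in self.retained_signature_genes if g not in self.mapping]
        if missing:
            raise ValidationError(f"retained signature genes without controls: {missing[:5]}")


@dataclass
class ScoreMatrix:
    """Cells × signatures score values produced by one scoring method."""

    values: np.ndarray
    cell_ids: list[str]
    signature_names: list[str]
    method: str
    provenance: Mapping | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("score values must be 2-D (cells × signatures)")
        if self.values.shape != (len(self.cell_ids), len(self.signature_names)):
            raise ValidationError(
                f"score shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.signature_names)} signatures"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("score matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.signature_names)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Check all ExpressionMatrix invariants; return the matrix unchanged.

    Raises :class:`ValidationError` naming the first offending entry for
    negative/non-finite values or the duplicated identifier.
    """
    n, p = matrix.values.shape
    if len(matrix.cell_ids) != n:
        raise ValidationError(f"{len(matrix.cell_ids)} cell ids for {n} rows")
    if len(matrix.gene_ids) != p:
        raise ValidationError(f"{len(matrix.gene_ids)} gene ids for {p} columns")
    dup = _first_duplicate(matrix.cell_ids)
    if dup is not None:
        raise ValidationError(f"duplicate cell id {dup!r}")
    dup = _first_duplicate(matrix.gene_ids)
    if dup is not None:
        raise ValidationError(f"duplicate gene id {dup!r}")

    if matrix.is_sparse:
        data = matrix.values.tocoo()
        bad = ~np.isfinite(data.data) | (data.data < 0)
        if np.any(bad):
            k = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"invalid value {data.data[k]} at cell "
                f"{matrix.cell_ids[data.row[k]]!r}, gene {matrix.gene_ids[data.col[k]]!r}"
            )
    else:
        vals = np.asarray(matrix.values)
        bad = ~np.isfinite(vals) | (vals < 0)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid value {vals[i, j]} at cell "
                f"{matrix.cell_ids[i]!r}, gene {matrix.gene_ids[j]!r}"
            )
    if matrix.cell_metadata is not None and len(matrix.cell_metadata) != n:
        raise ValidationError("cell_metadata length does not match number of cells")
    return matrix


def intersect_signature(
    sig: GeneSignature, matrix: ExpressionMatrix
) -> tuple[GeneSignature, list[str]]:
    """Restrict a signature to genes present in the matrix (order preserved).

    Returns the reduced signature and the list of dropped (absent) genes.
    Raises :class:`ValidationError` if no signature gene is in the matrix.
    """
    present = [g for g in sig.genes if matrix.has_gene(g)]
    dropped = [g for g in sig.genes if not matrix.has_gene(g)]
    if not present:
        raise ValidationError(f"signature {sig.name!r} has no genes in matrix")
    if dropped:
        logger.warning(
            "signature %r: dropped %d gene(s) absent from matrix: %s",
            sig.name, len(dropped), dropped[:10],
        )
    return GeneSignature(name=sig.name, genes=present), dropped
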