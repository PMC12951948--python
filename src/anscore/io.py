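"""File I/O: expression matrices (dense CSV/TSV, MatrixMarket), GMT gene
sets, per-cell metadata, and score tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import ExpressionMatrix, GeneSignature, ScoreMatrix, ValidationError, validate_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_signatures_gmt",
    "write_signatures_gmt",
    "read_cell_metadata",
    "write_scores",
    "read_scores",
]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValidationError(f"cannot infer matrix format from {path.name!r}")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.txt"), Path(f"{stem}_cells.txt")


def _read_ids(path: Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_expression(
    path,
    fmt: str | None = None,
    genes_file=None,
    cells_file=None,
    transpose: bool = False,
    metadata=None,
) -> ExpressionMatrix:
    """Read a cells × genes matrix from dense CSV/TSV or MatrixMarket MTX.

    Dense files carry cell ids in the first column and gene ids in the
    header. MTX needs one-id-per-line gene and cell files (defaults:
    ``<stem>_genes.txt`` / ``<stem>_cells.txt`` next to the matrix).
    ``transpose=True`` declares the file as genes × cells and flips it.
    An optional metadata TSV (indexed by cell id) is attached.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        mat = scipy.io.mmread(path).tocsr()
        gpath, cpath = _sidecar_paths(path)
        genes = _read_ids(genes_file or gpath)
        cells = _read_ids(cells_file or cpath)
        if transpose:
            mat = mat.T.tocsr()
        n, p = mat.shape
        if len(cells) != n or len(genes) != p:
            raise ValidationError(
                f"matrix is {n} cells × {p} genes but id files list "
                f"{len(cells)} cells and {len(genes)} genes"
            )
        matrix = ExpressionMatrix(values=mat, cell_ids=cells, gene_ids=genes)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0,
                         float_precision="round_trip")
        if transpose:
            df = df.T
        matrix = ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
        )
    else:
        raise ValidationError(f"unknown matrix format {fmt!r}")

    if metadata is not None:
        meta = read_cell_metadata(metadata)
        missing = [c for c in matrix.cell_ids if c not in meta.index]
        if missing:
            raise ValidationError(f"metadata lacks {len(missing)} cell id(s), e.g. {missing[:3]}")
        matrix.cell_metadata = meta.loc[matrix.cell_ids].reset_index(drop=True)
    return validate_matrix(matrix)


def write_expression(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix as dense CSV/TSV or MTX (+ gene/cell id sidecars)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        vals = matrix.values if matrix.is_sparse else sp.csr_matrix(np.asarray(matrix.values))
        scipy.io.mmwrite(str(path), vals)
        gpath, cpath = _sidecar_paths(path)
        gpath.write_text("\n".join(matrix.gene_ids) + "\n")
        cpath.write_text("\n".join(matrix.cell_ids) + "\n")
    elif fmt in ("csv", "tsv"):
        pd.DataFrame(
            matrix.dense(), index=matrix.cell_ids, columns=matrix.gene_ids
        ).to_csv(path, sep="," if fmt == "csv" else "\t")
    else:
        raise ValidationError(f"unknown matrix format {fmt!r}")


def read_signatures_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Order within a line is preserved; duplicate genes are removed with a
    warning. Lines with fewer than three fields are an error (with the line
    number); an empty file yields an empty list with a warning.
    """
    sigs: list[GeneSignature] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}: line {lineno} has {len(fields)} field(s); "
                "expected name, description, and at least one gene"
            )
        name, genes = fields[0], [g for g in fields[2:] if g]
        seen, uniq = set(), []
        for g in genes:
            if g in seen:
                continue
            seen.add(g)
            uniq.append(g)
        if len(uniq) < len(genes):
            logger.warning("%s: line %d (%r) had duplicate genes; deduplicated", path, lineno, name)
        sigs.append(GeneSignature(name=name, genes=uniq))
    if not sigs:
        logger.warning("%s: no signatures found", path)
    return sigs


def write_signatures_gmt(signatures: list[GeneSignature], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def read_cell_metadata(path) -> pd.DataFrame:
    """TSV with a ``cell_id`` column (or the first column as cell id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" in df.columns:
        df = df.set_index("cell_id")
    else:
        df = df.set_index(df.columns[0])
    return df


def write_scores(scores: ScoreMatrix, path) -> None:
    """Score TSV: cells as rows (cell_id first column), signatures as
    columns, floats at full precision so downstream argmax is unperturbed."""
    df = scores.to_frame()
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_scores(path, method: str = "unknown") -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ScoreMatrix(
        values=df.to_numpy(dtype=float),
        cell_ids=[str(i) for i in df.index],
        signature_names=[str(c) for c in df.columns],
        method=method,
    )
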