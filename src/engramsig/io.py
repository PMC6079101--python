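"""Reading and writing expression matrices and metadata tables.

Matrices are genes x nuclei on the log2(TPM+1) scale, held as a pandas
DataFrame with unique gene index and nucleus columns.  Two on-disk dialects
are supported: a dense tab-separated table, and MatrixMarket coordinate
format with sidecar gene/nucleus name files (``<stem>.genes.txt`` and
``<stem>.nuclei.txt`` next to the ``.mtx``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["read_matrix", "write_matrix", "read_metadata", "validate_matrix"]

_REQUIRED_METADATA = [
    "condition", "population", "fos_protein", "arc_protein",
    "total_aligned_reads", "detected_genes",
]


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check invariants: unique identifiers, numeric non-negative values."""
    dup_g = matrix.index[matrix.index.duplicated()].unique().tolist()
    if dup_g:
        raise ValueError(f"duplicate gene identifiers: {dup_g[:10]}")
    dup_n = matrix.columns[matrix.columns.duplicated()].unique().tolist()
    if dup_n:
        raise ValueError(f"duplicate nucleus identifiers: {dup_n[:10]}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("matrix contains non-numeric values")
    if np.isnan(values).any():
        bad = matrix.index[np.isnan(values).any(axis=1)][:10].tolist()
        raise ValueError(f"matrix contains missing values in genes: {bad}")
    if (values < 0).any():
        bad = matrix.index[(values < 0).any(axis=1)][:10].tolist()
        raise ValueError(f"negative expression values in genes: {bad}")
    return matrix


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".nuclei.txt")


def read_matrix(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a genes x nuclei matrix from TSV or MatrixMarket.

    ``format`` is inferred from the extension when omitted ('.mtx' ->
    MatrixMarket, anything else -> TSV).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        genes_path, nuclei_path = _sidecars(path)
        for p in (genes_path, nuclei_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar name file: {p}")
        genes = genes_path.read_text().splitlines()
        nuclei = nuclei_path.read_text().splitlines()
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        m = np.asarray(m, dtype=float)
        if m.shape != (len(genes), len(nuclei)):
            raise ValueError(
                f"matrix shape {m.shape} does not match sidecar names "
                f"({len(genes)} genes, {len(nuclei)} nuclei)"
            )
        df = pd.DataFrame(m, index=genes, columns=nuclei)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return validate_matrix(df)


def write_matrix(matrix: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as TSV (full precision) or MatrixMarket + sidecars."""
    validate_matrix(matrix)
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        matrix.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "mtx":
        genes_path, nuclei_path = _sidecars(path)
        sparse = scipy.sparse.coo_matrix(matrix.to_numpy())
        scipy.io.mmwrite(str(path), sparse, precision=17)
        genes_path.write_text("\n".join(map(str, matrix.index)) + "\n")
        nuclei_path.write_text("\n".join(map(str, matrix.columns)) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_metadata(path: str | Path, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a per-nucleus metadata table; optionally check matrix coverage."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    missing_cols = [c for c in _REQUIRED_METADATA if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    if matrix is not None:
        uncovered = [n for n in matrix.columns if n not in meta.index]
        if uncovered:
            raise ValueError(f"nuclei missing from metadata: {uncovered[:10]}")
    return meta
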