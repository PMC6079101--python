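"""Nucleus-level quality and label-consistency filters.

Two filters are applied to sequenced nuclei before analysis.  The depth
filter removes nuclei below minimum total aligned reads and detected gene
counts (values *below* the cutoff fail; nuclei exactly at the cutoff are
retained).  The Arc-concordance filter removes nuclei that were sorted as
FOS-protein-negative but express Arc mRNA above a threshold, i.e. cells
that were likely active recently but have already degraded FOS protein;
FOS+ nuclei are never touched by this rule, and the comparison is a strict
inequality.  Both filters are idempotent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "qc_filter_nuclei",
    "exclude_arc_discordant",
    "resolve_arc_gene",
    "exclude_cluster_outliers",
]


@dataclass
class QCReport:
    """Summary of one filtering pass over a set of nuclei."""

    n_input: int
    n_fail_reads: int = 0
    n_fail_genes: int = 0
    n_fail_arc_rule: int = 0
    retained_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_fail_reads": self.n_fail_reads,
            "n_fail_genes": self.n_fail_genes,
            "n_fail_arc_rule": self.n_fail_arc_rule,
            "n_retained": self.n_retained,
        }


def _check_metadata(matrix: pd.DataFrame, metadata: pd.DataFrame,
                    required: list[str]) -> pd.DataFrame:
    missing = [n for n in matrix.columns if n not in metadata.index]
    if missing:
        raise ValueError(f"nuclei missing from metadata: {missing[:10]}")
    meta = metadata.loc[matrix.columns]
    for col in required:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column: {col}")
        if meta[col].isna().any():
            bad = meta.index[meta[col].isna()][:10].tolist()
            raise ValueError(f"metadata field {col!r} missing for nuclei: {bad}")
    return meta


def qc_filter_nuclei(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    min_reads: int = 100_000,
    min_genes: int = 4000,
) -> QCReport:
    """Remove nuclei with too few aligned reads or detected genes.

    Nuclei with ``total_aligned_reads`` < ``min_reads`` or
    ``detected_genes`` < ``min_genes`` are dropped; boundary values pass.
    """
    meta = _check_metadata(matrix, metadata,
                           ["total_aligned_reads", "detected_genes"])
    fail_reads = meta["total_aligned_reads"].to_numpy() < min_reads
    fail_genes = meta["detected_genes"].to_numpy() < min_genes
    keep = ~(fail_reads | fail_genes)
    return QCReport(
        n_input=len(meta),
        n_fail_reads=int(fail_reads.sum()),
        n_fail_genes=int(fail_genes.sum()),
        retained_ids=list(meta.index[keep]),
    )


def resolve_arc_gene(matrix: pd.DataFrame, arc_gene: str | None = None) -> str:
    """Find the Arc gene row by case-insensitive symbol match (overridable)."""
    if arc_gene is not None:
        if arc_gene not in matrix.index:
            raise ValueError(f"Arc override gene {arc_gene!r} absent from matrix")
        return arc_gene
    hits = [g for g in matrix.index if str(g).lower() == "arc"]
    if not hits:
        raise ValueError("Arc gene not found in matrix; pass arc_gene explicitly")
    return hits[0]


def exclude_arc_discordant(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    arc_threshold: float = 2.5,
    arc_gene: str | None = None,
) -> QCReport:
    """Remove FOS-protein-negative nuclei with Arc mRNA above threshold.

    The rule is strict (> ``arc_threshold`` on the log2(TPM+1) scale) and
    applies only to nuclei with ``fos_protein == 'neg'``.
    """
    meta = _check_metadata(matrix, metadata, ["fos_protein"])
    arc = resolve_arc_gene(matrix, arc_gene)
    arc_expr = matrix.loc[arc].to_numpy(dtype=float)
    fail = (meta["fos_protein"].to_numpy() == "neg") & (arc_expr > arc_threshold)
    return QCReport(
        n_input=len(meta),
        n_fail_arc_rule=int(fail.sum()),
        retained_ids=list(meta.index[~fail]),
    )


def exclude_cluster_outliers(
    matrix: pd.DataFrame,
    labels: pd.Series,
    min_silhouette: float = -0.25,
) -> QCReport:
    """Optional extreme-outlier filter: drop nuclei whose silhouette against
    their own cluster falls below ``min_silhouette``.  Off by default in the
    pipeline; the original study removed clustering-based extreme outliers
    without publishing a rule, so this is a conservative stand-in.
    """
    from sklearn.metrics import silhouette_samples

    labels = labels.loc[matrix.columns]
    if labels.nunique() < 2:
        return QCReport(n_input=matrix.shape[1],
                        retained_ids=list(matrix.columns))
    sil = silhouette_samples(matrix.to_numpy().T, labels.to_numpy())
    keep = sil >= min_silhouette
    return QCReport(n_input=matrix.shape[1],
                    retained_ids=list(np.asarray(matrix.columns)[keep]))
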