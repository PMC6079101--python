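"""Local functional-enrichment testing and GO-based gene–gene distances.

Enrichment is an upper-tail hypergeometric test of a gene set against
user-supplied gene→term annotations, with Benjamini–Hochberg correction
across terms.  Gene similarity is a weighted cosine over term-membership
vectors, where each term is weighted by a function of its number of parent
terms so that deeper (more specific) terms contribute more.  Both operate on
flat two-column tables rather than a parsed ontology, so any source of
annotations and parent counts can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GOAnnotation",
    "enrichment_test",
    "go_gene_distance",
    "export_network",
    "default_term_weight",
]


def default_term_weight(parent_count: np.ndarray) -> np.ndarray:
    """Default term weight: log2(1 + parent count), up-weighting specific terms."""
    return np.log2(1.0 + np.asarray(parent_count, dtype=float))


@dataclass
class GOAnnotation:
    """Gene→term memberships plus a parent count per term.

    ``gene_terms`` maps each annotated gene to a set of term identifiers;
    ``parent_count`` maps each term to its (non-negative) number of parent
    terms in the ontology graph.  ``term_names`` is optional descriptive text.
    """

    gene_terms: dict[str, frozenset[str]]
    parent_count: dict[str, int]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        referenced = set().union(*self.gene_terms.values()) if self.gene_terms else set()
        missing = referenced - set(self.parent_count)
        if missing:
            raise ValueError(
                f"terms without a parent-count entry: {sorted(missing)[:10]}"
            )
        if any(c < 0 for c in self.parent_count.values()):
            raise ValueError("parent counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_terms)

    @property
    def terms(self) -> list[str]:
        return sorted(self.parent_count)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())

    @classmethod
    def from_tables(
        cls, gene_term: pd.DataFrame, term_parents: pd.DataFrame
    ) -> "GOAnnotation":
        """Build from a (gene, term) table and a (term, parent_count) table."""
        gt: dict[str, set[str]] = {}
        for g, t in zip(gene_term.iloc[:, 0], gene_term.iloc[:, 1]):
            gt.setdefault(str(g), set()).add(str(t))
        pc = {
            str(t): int(c)
            for t, c in zip(term_parents.iloc[:, 0], term_parents.iloc[:, 1])
        }
        return cls({g: frozenset(ts) for g, ts in gt.items()}, pc)

    @classmethod
    def read_tsv(cls, gene_term_path: str | Path, term_parent_path: str | Path) -> "GOAnnotation":
        gt = pd.read_csv(gene_term_path, sep="\t")
        tp = pd.read_csv(term_parent_path, sep="\t")
        return cls.from_tables(gt, tp)

    def write_tsv(self, gene_term_path: str | Path, term_parent_path: str | Path) -> None:
        rows = [(g, t) for g in self.genes for t in sorted(self.gene_terms[g])]
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
            gene_term_path, sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.parent_count.items()), columns=["term", "parent_count"]
        ).to_csv(term_parent_path, sep="\t", index=False)


def enrichment_test(
    gene_set: Iterable[str],
    annotation: GOAnnotation,
    universe: Iterable[str],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``gene_set`` within ``universe``.

    For a term annotating ``n`` universe genes, the p-value is the upper-tail
    hypergeometric probability of drawing at least the observed overlap when
    ``len(gene_set)`` genes are sampled from the universe without replacement.
    BH adjustment runs across the tested terms (overlap >= ``min_overlap`` by
    default, the common enrichment convention; set ``min_overlap=0`` to test
    every term).
    """
    universe = set(map(str, universe))
    gene_set = set(map(str, gene_set))
    if not universe:
        raise ValueError("universe is empty")
    if not gene_set:
        raise ValueError("gene_set is empty")
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[:10]
        raise ValueError(f"gene_set not contained in universe: {extra}")

    M, N = len(universe), len(gene_set)
    rows = []
    for term in annotation.terms:
        members = {g for g, ts in annotation.gene_terms.items() if term in ts}
        n = len(members & universe)
        k = len(members & gene_set)
        if n == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append((term, n, k, p))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_raw"])
    out = out[out["overlap"] >= min_overlap].reset_index(drop=True)
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
        out = out.sort_values(["p_raw", "term"], kind="stable").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def go_gene_distance(
    genes: Sequence[str],
    annotation: GOAnnotation,
    weight_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Weighted-cosine distance matrix between genes based on shared GO terms.

    Each gene is represented as an indicator vector over terms scaled by a
    per-term weight w_t = ``weight_fn``(parent_count_t); the distance is
    1 − cosine similarity, in [0, 1] for non-negative weights.  Identical
    annotation sets give distance 0, disjoint sets give 1.
    """
    genes = [str(g) for g in genes]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in input list")
    missing = [g for g in genes if not annotation.terms_of(g)]
    if missing:
        raise ValueError(f"genes without any annotation: {missing[:10]}")
    weight_fn = weight_fn or default_term_weight

    terms = annotation.terms
    t_index = {t: i for i, t in enumerate(terms)}
    w = weight_fn(np.array([annotation.parent_count[t] for t in terms]))
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("term weights must be non-negative")

    vecs = np.zeros((len(genes), len(terms)))
    for i, g in enumerate(genes):
        for t in annotation.terms_of(g):
            vecs[i, t_index[t]] = w[t_index[t]]
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        bad = [genes[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"genes with zero total term weight: {bad[:10]}")

    dist = squareform(pdist(vecs, metric="cosine"))
    # floating error can leave tiny negatives or >1 excursions; identical
    # vectors must come out at exactly zero
    dist[dist < 1e-12] = 0.0
    np.clip(dist, 0.0, 1.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=genes, columns=genes)


def export_network(
    distances: pd.DataFrame,
    edge_threshold: float,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Undirected edge list of gene pairs with distance <= ``edge_threshold``.

    Written (if ``path`` is given) as a three-column tab-separated
    interaction file: gene_a, gene_b, distance.
    """
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValueError("edge_threshold must be in [0, 1]")
    genes = list(distances.index)
    vals = distances.to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if vals[i, j] <= edge_threshold:
                rows.append((genes[i], genes[j], float(vals[i, j])))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "distance"])
    if path is not None:
        edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return edges
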