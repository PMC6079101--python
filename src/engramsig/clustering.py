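"""Cell-type identification by hierarchical iterative clustering + refinement.

The workflow embeds nuclei in two dimensions with t-SNE, bisects the
embedding by complete-linkage hierarchical clustering, validates the
bisection by two-group differential expression, and recurses into each
branch.  Recursion stops when a proposed split can no longer support
differential expression (fewer than ``min_de_genes`` genes at the chosen
FDR) or would create a branch smaller than ``min_leaf``; the node then
becomes a leaf cluster.  A refinement step then fits two successive random
forests, keeping genes above a Mean-Decrease-Gini cutoff each time, and
re-predicts every nucleus's cluster out-of-bag, yielding a per-cluster
precision (the fraction of nuclei whose out-of-bag prediction recovers
their cluster).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from ._rf import fit_forest, mean_decrease_gini, oob_predictions
from .diffexp import ROTSParams, rots_test

__all__ = [
    "ClusterTree",
    "ClusterPrecision",
    "embed_2d",
    "iterative_cluster",
    "refine_clusters_rf",
    "name_clusters",
]


def embed_2d(
    matrix: pd.DataFrame,
    initial_dims: int = 20,
    perplexity: float = 17.0,
    theta: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """t-SNE embedding of nuclei into two dimensions.

    The matrix is first reduced to ``initial_dims`` principal components.
    ``theta`` = 0 selects the exact gradient; positive values use the
    Barnes–Hut approximation with that angle.  Deterministic given ``seed``.
    """
    n = matrix.shape[1]
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} nuclei cannot support perplexity {perplexity}; "
            f"reduce perplexity below {n / 3:.1f}"
        )
    X = matrix.to_numpy(dtype=float).T
    k = min(initial_dims, n - 1, matrix.shape[0])
    X = PCA(n_components=k, random_state=seed).fit_transform(X)
    if theta == 0.0:
        tsne = TSNE(n_components=2, perplexity=perplexity, method="exact",
                    random_state=seed, init="pca")
    else:
        tsne = TSNE(n_components=2, perplexity=perplexity, method="barnes_hut",
                    angle=theta, random_state=seed, init="pca")
    emb = tsne.fit_transform(X)
    return pd.DataFrame(emb, index=matrix.columns, columns=["tsne1", "tsne2"])


@dataclass
class ClusterTree:
    """Binary split hierarchy; leaves partition the input nuclei."""

    nodes: list[dict] = field(default_factory=list)
    labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def n_leaves(self) -> int:
        return int(self.labels.nunique())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"nodes": self.nodes, "labels": self.labels.to_dict()}, indent=1
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def iterative_cluster(
    matrix: pd.DataFrame,
    de_alpha: float = 0.05,
    min_de_genes: int = 10,
    min_leaf: int = 10,
    seed: int = 0,
    de_params: ROTSParams | None = None,
    perplexity: float = 17.0,
    initial_dims: int = 20,
    theta: float = 0.0,
    top_genes: int = 10,
) -> ClusterTree:
    """Recursive embed → bisect → test-by-DE clustering of nuclei.

    Each candidate bisection (k = 2 cut of a complete-linkage, Euclidean
    dendrogram on the 2-D embedding) is accepted only if differential
    expression between the two branches yields at least ``min_de_genes``
    genes at adjusted p < ``de_alpha`` and both branches have at least
    ``min_leaf`` nuclei.  The split test uses a reduced bootstrap count by
    default (B = 100) to keep deep recursions affordable.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty matrix")
    de_params = de_params or ROTSParams(B=100, n_perm=500)
    tree = ClusterTree()
    labels = pd.Series(-1, index=matrix.columns, dtype=int)
    state = {"next_leaf": 0, "next_node": 0}

    def make_leaf(ids: pd.Index) -> None:
        lab = state["next_leaf"]
        state["next_leaf"] += 1
        labels.loc[ids] = lab
        tree.nodes.append({"id": f"leaf{lab}", "leaf": True, "label": lab,
                           "members": list(map(str, ids))})

    def split(ids: pd.Index, depth: int) -> None:
        n = len(ids)
        if n < 2 * min_leaf or n < 8:
            make_leaf(ids)
            return
        sub = matrix[ids]
        perp = min(perplexity, (n - 1) / 3.0)
        node_seed = (seed + 7919 * depth + 104729 * state["next_node"]) % (2**31)
        emb = embed_2d(sub, initial_dims=initial_dims, perplexity=perp,
                       theta=theta, seed=node_seed)
        Z = linkage(emb.to_numpy(), method="complete", metric="euclidean")
        cut = fcluster(Z, t=2, criterion="maxclust")
        ids_a, ids_b = ids[cut == 1], ids[cut == 2]
        if min(len(ids_a), len(ids_b)) < max(min_leaf, 2):
            make_leaf(ids)
            return
        de = rots_test(
            matrix[ids_a], matrix[ids_b],
            ROTSParams(alpha1=de_params.alpha1, alpha2=de_params.alpha2,
                       B=de_params.B, K_grid=de_params.K_grid,
                       seed=node_seed, n_perm=de_params.n_perm,
                       exact_limit=de_params.exact_limit),
        )
        sig = de[de["p_adj"] < de_alpha].sort_values("p_adj", kind="stable")
        node_id = f"node{state['next_node']}"
        state["next_node"] += 1
        tree.nodes.append({
            "id": node_id, "leaf": False,
            "n_a": int(len(ids_a)), "n_b": int(len(ids_b)),
            "n_significant": int(len(sig)),
            "top_genes": list(map(str, sig.index[:top_genes])),
        })
        if len(sig) < min_de_genes:
            tree.nodes.pop()
            make_leaf(ids)
            return
        split(ids_a, depth + 1)
        split(ids_b, depth + 1)

    split(matrix.columns, depth=0)
    tree.labels = labels.astype(int)
    return tree


@dataclass
class ClusterPrecision:
    """Out-of-bag per-cluster precision plus the predictive gene set."""

    precision: dict  # cluster label (int leaf or prior-knowledge name) -> [0, 1]
    predictive_genes: pd.DataFrame  # index gene, column 'gini'


def refine_clusters_rf(
    matrix: pd.DataFrame,
    labels: pd.Series | ClusterTree,
    min_total_expression: float = 10.0,
    gini_cutoff: float = 1.0,
    n_trees: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, ClusterPrecision]:
    """Random-forest refinement of cluster labels with out-of-bag precision.

    Genes with less than ``min_total_expression`` TPM summed over all nuclei
    (on the linear scale, 2^x - 1) are excluded up front.  Two successive
    forest fits each keep genes whose Mean-Decrease-Gini exceeds
    ``gini_cutoff``; the surviving set drives a final out-of-bag
    re-prediction of every nucleus's label.  Per-cluster precision is the
    fraction of that cluster's nuclei recovered out-of-bag.
    """
    if isinstance(labels, ClusterTree):
        labels = labels.labels
    labels = labels.loc[matrix.columns]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("refinement needs at least 2 clusters")
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise ValueError(f"clusters with a single nucleus: {singletons}")

    tpm_sum = (2.0 ** matrix.to_numpy(dtype=float) - 1.0).sum(axis=1)
    kept = matrix.index[tpm_sum >= min_total_expression]
    if len(kept) == 0:
        raise ValueError("no genes pass the minimum-expression filter")

    y = labels.to_numpy()
    genes = kept
    for round_ in range(2):
        X = matrix.loc[genes].to_numpy(dtype=float).T
        forest = fit_forest(X, y, n_trees, seed + round_)
        gini = mean_decrease_gini(forest)
        keep = gini > gini_cutoff
        if not keep.any():
            raise ValueError(
                f"no genes retained at Gini cutoff {gini_cutoff} (round {round_ + 1})"
            )
        genes = genes[keep]

    X = matrix.loc[genes].to_numpy(dtype=float).T
    forest = fit_forest(X, y, n_trees, seed + 2, oob=True)
    refined = oob_predictions(forest, y)
    gini = mean_decrease_gini(forest)

    precision = {
        c: float((refined[y == c] == c).mean()) for c in np.unique(y)
    }
    pred_genes = pd.DataFrame(
        {"gini": gini}, index=genes
    ).sort_values("gini", ascending=False, kind="stable")
    refined_series = pd.Series(refined, index=matrix.columns, name="refined_label")
    return refined_series, ClusterPrecision(precision, pred_genes)


def name_clusters(
    labels: pd.Series,
    matrix: pd.DataFrame,
    marker_table: dict[str, list[str]],
) -> dict[int, str]:
    """Assign each cluster the prior-knowledge name whose marker genes have
    the highest mean expression within the cluster."""
    names = {}
    for c in sorted(labels.unique()):
        ids = labels.index[labels == c]
        best, best_val = "unknown", -np.inf
        for name, markers in marker_table.items():
            present = [g for g in markers if g in matrix.index]
            if not present:
                continue
            val = float(matrix.loc[present, ids].to_numpy().mean())
            if val > best_val:
                best, best_val = name, val
        names[int(c)] = best
    return names
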