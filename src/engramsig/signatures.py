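"""Temporal gene groups, late-signature scoring and activity-state labels.

Activity-responsive genes are grouped by which of three reference
comparisons against home cage they reach significance in (1 h FOS+, 4 h
ARC+FOS-, 5 h ARC+FOS-).  The seven non-empty significance patterns define
groups 1-7; the early signature is group 1 ({1h} only), the sustained
signature group 5 ({1h, 4h, 5h}) and the late signature group 4
({4h, 5h} but not 1h).  Each nucleus is scored by its projection on the
first principal component of the late-signature genes; thresholding that
score labels nuclei early vs late, and — applied to double-exposure
ARC+FOS+ nuclei — Newly Activated vs Reactivated.  A simplified trajectory
pseudotime orders nuclei along a minimum-spanning-tree diameter path in a
2-D independent-component space of the activity genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr, ttest_ind
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA

__all__ = [
    "PATTERN_TO_GROUP",
    "TemporalGroupAssignment",
    "assign_temporal_groups",
    "late_signature_score",
    "classify_activity_state",
    "reactivation_labels",
    "activity_pseudotime",
]

#: significance pattern across (1h, 4h, 5h) → temporal group number
PATTERN_TO_GROUP: dict[frozenset[str], int] = {
    frozenset({"1h"}): 1,
    frozenset({"5h"}): 2,
    frozenset({"4h"}): 3,
    frozenset({"4h", "5h"}): 4,
    frozenset({"1h", "4h", "5h"}): 5,
    frozenset({"1h", "5h"}): 6,
    frozenset({"1h", "4h"}): 7,
}


@dataclass
class TemporalGroupAssignment:
    """Per-gene temporal group (1-7, or 0 for not significant anywhere)."""

    groups: pd.Series
    alpha: float
    comparisons: tuple[str, str, str] = ("1h_vs_HC", "4h_vs_HC", "5h_vs_HC")

    def genes_in(self, group: int) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def early_genes(self) -> list[str]:
        return self.genes_in(1)

    @property
    def sustained_genes(self) -> list[str]:
        return self.genes_in(5)

    @property
    def late_genes(self) -> list[str]:
        return self.genes_in(4)


def assign_temporal_groups(
    de_1h: pd.DataFrame,
    de_4h: pd.DataFrame,
    de_5h: pd.DataFrame,
    alpha: float = 0.05,
) -> TemporalGroupAssignment:
    """Map each gene's significance pattern across the three comparisons to a
    temporal group.  The three DE tables must share one gene universe."""
    universe = de_1h.index
    for name, de in (("4h", de_4h), ("5h", de_5h)):
        if set(de.index) != set(universe):
            missing = sorted(set(universe) ^ set(de.index))[:10]
            raise ValueError(f"{name} comparison universe mismatch: {missing}")
    sig = {
        "1h": de_1h["p_adj"] < alpha,
        "4h": de_4h.loc[universe, "p_adj"] < alpha,
        "5h": de_5h.loc[universe, "p_adj"] < alpha,
    }
    groups = pd.Series(0, index=universe, dtype=int)
    for g in universe:
        pattern = frozenset(t for t in ("1h", "4h", "5h") if bool(sig[t][g]))
        if pattern:
            groups[g] = PATTERN_TO_GROUP[pattern]
    return TemporalGroupAssignment(groups=groups, alpha=alpha)


def late_signature_score(
    matrix: pd.DataFrame,
    late_genes: list[str],
) -> pd.Series:
    """Projection of each nucleus on PC1 of the late-signature genes.

    PCA runs on centered, unscaled log2(TPM+1) restricted to the late genes.
    The component sign is oriented so that nuclei with high summed
    late-gene expression score positive.
    """
    present = [g for g in late_genes if g in matrix.index]
    if len(present) < 2:
        raise ValueError(
            f"need >= 2 late-signature genes in the matrix, found {len(present)}"
        )
    X = matrix.loc[present].to_numpy(dtype=float).T
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("late-signature genes have zero variance across nuclei")
    pca = PCA(n_components=1, random_state=0)
    scores = pca.fit_transform(X)[:, 0]
    summed = X.sum(axis=1)
    corr = np.corrcoef(scores, summed)[0, 1] if np.std(summed) > 0 else 1.0
    if corr < 0:
        scores = -scores
    return pd.Series(scores, index=matrix.columns, name="pc_score")


def classify_activity_state(
    scores: pd.Series,
    threshold_policy: str = "two_means",
    threshold: float = 10.0,
) -> tuple[pd.Series, bool]:
    """Label nuclei early vs late from their late-signature PC score.

    ``fixed`` uses the supplied threshold with the boundary assigned to
    late; ``two_means`` splits the scores by 1-D 2-means and calls the
    higher-center cluster late.  Returns (labels, unimodal_warning); the
    warning is set under ``two_means`` when the center separation is below
    the pooled within-cluster SD (the split is then unreliable).
    """
    vals = scores.to_numpy(dtype=float)
    warn = False
    if threshold_policy == "fixed":
        labels = np.where(vals >= threshold, "late", "early")
    elif threshold_policy == "two_means":
        if np.ptp(vals) == 0.0:
            return pd.Series("early", index=scores.index, name="signature_label"), True
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(vals[:, None])
        hi = int(np.argmax(km.cluster_centers_[:, 0]))
        labels = np.where(km.labels_ == hi, "late", "early")
        centers = np.sort(km.cluster_centers_[:, 0])
        within = np.concatenate([
            vals[km.labels_ == c] - km.cluster_centers_[c, 0] for c in (0, 1)
        ])
        pooled_sd = float(np.sqrt(np.mean(within**2)))
        warn = (centers[1] - centers[0]) < pooled_sd
    else:
        raise ValueError("threshold_policy must be 'fixed' or 'two_means'")
    return pd.Series(labels, index=scores.index, name="signature_label"), warn


def reactivation_labels(
    signature_labels: pd.Series,
    metadata: pd.DataFrame,
    double_conditions: tuple[str, ...] = ("AA", "AC"),
) -> pd.Series:
    """Translate early/late signature labels into reactivity classes.

    Double-exposure ARC+FOS+ nuclei become NewlyActivated (early signature)
    or Reactivated (late signature); double-exposure ARC+FOS- nuclei are
    NotReactivated regardless of score.  Other nuclei get no label (NaN).
    """
    meta = metadata.loc[signature_labels.index]
    out = pd.Series(np.nan, index=signature_labels.index, dtype=object,
                    name="reactivity_label")
    double = meta["condition"].isin(double_conditions)
    pos = double & (meta["fos_protein"] == "pos") & (meta["arc_protein"] == "pos")
    neg = double & (meta["fos_protein"] == "neg") & (meta["arc_protein"] == "pos")
    out[pos & (signature_labels == "early")] = "NewlyActivated"
    out[pos & (signature_labels == "late")] = "Reactivated"
    out[neg] = "NotReactivated"
    return out


def _mst_diameter_path(dist: np.ndarray) -> np.ndarray:
    """Geodesic distances from one end of the MST diameter (per-node)."""
    mst = minimum_spanning_tree(dist)
    geo = shortest_path(mst, directed=False)
    start = int(np.argmax(geo[0]))
    end = int(np.argmax(geo[start]))
    return geo[start], geo[end]


def activity_pseudotime(
    matrix: pd.DataFrame,
    activity_genes: list[str],
    n_components: int = 2,
    seed: int = 0,
    anchor_gene: str = "Arc",
    groups: pd.Series | None = None,
    group_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Trajectory pseudotime of nuclei along an activity-state axis.

    Expression restricted to ``activity_genes`` is reduced to
    ``n_components`` independent components; a minimum spanning tree is
    built over nuclei in component space and pseudotime is the geodesic
    distance from one end of the tree's diameter path.  The root is chosen
    so that pseudotime increases with the anchor gene (Arc by default); if
    the anchor is absent or constant, summed activity-gene expression is
    used instead and flagged.  Student's t-tests are reported for each
    requested group pair.
    """
    present = [g for g in activity_genes if g in matrix.index]
    if len(present) < n_components:
        raise ValueError("too few activity genes present in the matrix")
    if matrix.shape[1] < n_components + 1:
        raise ValueError("too few nuclei for the requested components")
    X = matrix.loc[present].to_numpy(dtype=float).T
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("activity genes are constant; no trajectory exists")

    # reduce to the leading n-component subspace, then rotate to independent
    # axes; the trajectory metric keeps the variance-preserving scale (a
    # unit-variance whitening would inflate the noise axis to the signal's
    # scale and scramble the spanning tree)
    pca = PCA(n_components=n_components, random_state=seed)
    subspace = pca.fit_transform(X)
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-4)
    with warnings.catch_warnings():
        # the ICA rotation only orients the reported axes; non-convergence
        # does not affect the trajectory metric
        warnings.simplefilter("ignore")
        rotation = ica.fit(subspace).components_
    rotation /= np.linalg.norm(rotation, axis=1, keepdims=True)
    comps = subspace @ rotation.T  # pure rotation: distances preserved
    dist = squareform(pdist(comps))
    pt_a, pt_b = _mst_diameter_path(dist)

    flags = {"anchor_fallback": False}
    if anchor_gene in matrix.index and matrix.loc[anchor_gene].std() > 0:
        anchor = matrix.loc[anchor_gene].to_numpy(dtype=float)
    else:
        anchor = matrix.loc[present].sum(axis=0).to_numpy(dtype=float)
        flags["anchor_fallback"] = True
    rho_a = spearmanr(pt_a, anchor).statistic
    rho_b = spearmanr(pt_b, anchor).statistic
    pt = pt_a if (np.nan_to_num(rho_a) >= np.nan_to_num(rho_b)) else pt_b
    pseudotime = pd.Series(pt, index=matrix.columns, name="pseudotime")

    tests = pd.DataFrame(columns=["group_a", "group_b", "t", "p"])
    if groups is not None:
        groups = groups.loc[matrix.columns]
        pairs = group_pairs or list(_combinations(sorted(groups.dropna().unique()), 2))
        rows = []
        for a, b in pairs:
            res = ttest_ind(pseudotime[groups == a], pseudotime[groups == b])
            rows.append((a, b, float(res.statistic), float(res.pvalue)))
        tests = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    return pseudotime, tests, flags
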