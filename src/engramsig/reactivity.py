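"""Prediction of engram reactivation from the 4-5 h transcriptional signature.

Candidate predictive genes are the Reactivated-vs-NotReactivated
differentially expressed genes, filtered for consistent expression in
Reactivated nuclei (upregulated genes expressed above 1 log2(TPM+1) in at
least 80% of them, downregulated in at most 40%), with genes associated
with batch or differentially expressed at 1 h vs home cage excluded — the
point being to keep only signal that is already present hours before the
second exposure and is not an immediate-early artefact.  Two pairwise
random forests (Reactivated vs NewlyActivated, Reactivated vs
NotReactivated) are trained on a fixed number of nuclei per class; genes
with Mean-Decrease-Gini above a cutoff in either forest are pooled into a
three-way classifier whose held-out per-class error, ROC curves and
predicted reactivation probabilities are reported.  The model is then
applied to single-exposure 4/5-h nuclei to call a primed ("predicted
Reactivated", pR) state, and validated against a "reactivity component" —
the leading principal component of the full transcriptome that best
separates reactivity-defined subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal, pearsonr, ttest_ind
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from ._rf import fit_forest, mean_decrease_gini

__all__ = [
    "PredictiveGeneSet",
    "ReactivityModels",
    "ROCResult",
    "batch_association",
    "select_predictive_genes",
    "train_models",
    "evaluate_roc",
    "predict_primed",
    "reactivity_component",
]

CLASSES = ("NewlyActivated", "NotReactivated", "Reactivated")


@dataclass
class PredictiveGeneSet:
    """Selected predictive genes with direction and expression fraction."""

    table: pd.DataFrame  # index gene; columns direction, reactivated_fraction

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def batch_association(
    matrix: pd.DataFrame,
    batches: pd.Series,
    alpha: float = 0.05,
) -> list[str]:
    """Genes associated with batch: Kruskal–Wallis across batches, FDR < alpha."""
    batches = batches.loc[matrix.columns]
    groups = [matrix.columns[batches == b] for b in sorted(batches.unique())]
    if len(groups) < 2:
        return []
    X = matrix.to_numpy(dtype=float)
    idx = [np.flatnonzero(batches.to_numpy() == b) for b in sorted(batches.unique())]
    pvals = np.ones(X.shape[0])
    for i in range(X.shape[0]):
        samples = [X[i, j] for j in idx]
        if all(np.ptp(s) == 0 for s in samples):
            continue
        try:
            pvals[i] = kruskal(*samples).pvalue
        except ValueError:  # all values identical across batches
            pvals[i] = 1.0
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return list(matrix.index[p_adj < alpha])


def select_predictive_genes(
    de_r_vs_nr: pd.DataFrame,
    matrix: pd.DataFrame,
    reactivated_ids: list[str],
    de_1h_vs_hc: pd.DataFrame | None = None,
    batch_assoc_genes: list[str] | None = None,
    frac_up: float = 0.8,
    frac_down: float = 0.4,
    expr_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> PredictiveGeneSet:
    """Filter Reactivated-vs-NotReactivated DEGs down to putative predictors.

    Upregulated genes must be expressed (> ``expr_cutoff`` log2(TPM+1)) in
    at least ``frac_up`` of Reactivated nuclei; downregulated genes in at
    most ``frac_down``.  Genes significant in the 1 h vs HC comparison or
    associated with batch are excluded regardless of fraction.  The
    selection is order-invariant and idempotent.
    """
    if not reactivated_ids:
        raise ValueError("reactivated_ids is empty")
    missing = [g for g in de_r_vs_nr.index if g not in matrix.index]
    if missing:
        raise ValueError(f"DE genes absent from matrix: {missing[:10]}")

    candidates = de_r_vs_nr[de_r_vs_nr["p_adj"] < alpha]
    excluded = set(batch_assoc_genes or [])
    if de_1h_vs_hc is not None:
        excluded |= set(de_1h_vs_hc.index[de_1h_vs_hc["p_adj"] < alpha])

    expr = matrix.loc[candidates.index, list(reactivated_ids)].to_numpy(dtype=float)
    frac = (expr > expr_cutoff).mean(axis=1)
    rows = []
    for gene, direction, f in zip(candidates.index, candidates["direction"], frac):
        if gene in excluded:
            continue
        if direction == "up" and f >= frac_up:
            rows.append((gene, "up", float(f)))
        elif direction == "down" and f <= frac_down:
            rows.append((gene, "down", float(f)))
    if not rows:
        raise ValueError("no predictive genes survive the filters")
    table = (
        pd.DataFrame(rows, columns=["gene", "direction", "reactivated_fraction"])
        .set_index("gene")
        .sort_index()
    )
    return PredictiveGeneSet(table)


@dataclass
class ReactivityModels:
    """Trained pairwise and three-way forests with the train/test split."""

    model_i: object  # Reactivated vs NewlyActivated
    model_ii: object  # Reactivated vs NotReactivated
    model_three_way: object
    features_pairwise: list[str]
    features_pooled: list[str]
    train_ids: list[str]
    test_ids: list[str]
    per_class_error: dict[str, float]
    importances: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_trees: int = 0
    seed: int = 0

    def spec(self) -> dict:
        """Serializable description (features + hyperparameters); forests are
        reproducible from the spec because training is seeded."""
        return {
            "features_pairwise": self.features_pairwise,
            "features_pooled": self.features_pooled,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "per_class_error": self.per_class_error,
        }


def _features(matrix: pd.DataFrame, genes: list[str], ids) -> np.ndarray:
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValueError(f"model genes absent from matrix: {missing[:10]}")
    return matrix.loc[genes, ids].to_numpy(dtype=float).T


def _eliminate_features(
    matrix: pd.DataFrame,
    ids: list[str],
    y: np.ndarray,
    features: list[str],
    n_trees: int,
    seed: int,
    gini_cutoff: float = 0.4,
) -> list[str]:
    """Initial feature elimination: one three-way forest fit + Gini cutoff.

    A forest is fit on the full candidate set for the three-class training
    problem and only genes whose Mean-Decrease-Gini exceeds ``gini_cutoff``
    (the same cutoff used for pooling) are retained.  The three-way fit is
    what concentrates importance on genes that separate *any* pair of
    classes, so both the on/off predictive genes and the graded late-program
    genes survive.  If nothing clears the cutoff the candidate set is
    returned unchanged (elimination then has no bite rather than emptying
    the model).
    """
    X = _features(matrix, features, ids)
    forest = fit_forest(X, y, n_trees, seed)
    gini = mean_decrease_gini(forest)
    kept = [g for g, v in zip(features, gini) if v > gini_cutoff]
    return kept if kept else list(features)


def train_models(
    matrix: pd.DataFrame,
    labels: pd.Series,
    genes: PredictiveGeneSet | list[str],
    n_train_per_class: int = 15,
    n_trees: int = 10_000,
    gini_pool_cutoff: float = 0.4,
    seed: int = 0,
    feature_elimination: bool = True,
) -> ReactivityModels:
    """Train the pairwise and pooled three-way reactivity forests.

    ``labels`` maps nucleus → class in {NewlyActivated, NotReactivated,
    Reactivated}.  ``n_train_per_class`` nuclei per class are drawn for
    training; the rest form the held-out test set (train and test are
    disjoint by construction).  An initial feature-elimination pass (one
    three-way forest fit, genes above the Gini cutoff kept; see
    ``_eliminate_features``) can be disabled.  Pairwise forests are fit on
    the surviving gene set; genes exceeding
    ``gini_pool_cutoff`` in either are pooled for the three-way forest,
    whose per-class held-out error is reported.
    """
    gene_list = genes.genes if isinstance(genes, PredictiveGeneSet) else list(genes)
    labels = labels.dropna()
    labels = labels[labels.isin(CLASSES)]
    rng = np.random.default_rng(seed)

    train_ids: list[str] = []
    for cls in CLASSES:
        ids = labels.index[labels == cls]
        if len(ids) < n_train_per_class + 1:
            raise ValueError(
                f"class {cls} has {len(ids)} nuclei; needs >= {n_train_per_class + 1}"
            )
        chosen = rng.choice(len(ids), size=n_train_per_class, replace=False)
        train_ids.extend(ids[sorted(chosen)])
    test_ids = [i for i in labels.index if i not in set(train_ids)]
    y_train = labels.loc[train_ids]

    features = sorted(gene_list)
    if feature_elimination and len(features) > 5:
        features = _eliminate_features(
            matrix, train_ids, y_train.to_numpy(), features, n_trees, seed + 11,
            gini_cutoff=gini_pool_cutoff,
        )

    def pairwise(cls_a: str, cls_b: str, offset: int):
        ids = [i for i in train_ids if labels[i] in (cls_a, cls_b)]
        X = _features(matrix, features, ids)
        forest = fit_forest(X, labels.loc[ids].to_numpy(), n_trees, seed + offset)
        return forest, mean_decrease_gini(forest)

    model_i, gini_i = pairwise("Reactivated", "NewlyActivated", 13)
    model_ii, gini_ii = pairwise("Reactivated", "NotReactivated", 17)

    pooled = sorted(
        g for g, gi, gii in zip(features, gini_i, gini_ii)
        if gi > gini_pool_cutoff or gii > gini_pool_cutoff
    )
    if not pooled:
        raise ValueError(
            f"pooled predictive set is empty at Gini cutoff {gini_pool_cutoff}"
        )

    X3 = _features(matrix, pooled, train_ids)
    model_three = fit_forest(X3, y_train.to_numpy(), n_trees, seed + 19)

    X_test = _features(matrix, pooled, test_ids)
    pred = model_three.predict(X_test)
    y_test = labels.loc[test_ids].to_numpy()
    per_class_error = {
        cls: float((pred[y_test == cls] != cls).mean()) for cls in CLASSES
    }

    importances = pd.DataFrame(
        {"gini_i": gini_i, "gini_ii": gini_ii}, index=features
    )
    importances["pooled"] = importances.index.isin(pooled)
    return ReactivityModels(
        model_i=model_i, model_ii=model_ii, model_three_way=model_three,
        features_pairwise=features, features_pooled=pooled,
        train_ids=list(train_ids), test_ids=list(test_ids),
        per_class_error=per_class_error, importances=importances,
        n_trees=n_trees, seed=seed,
    )


@dataclass
class ROCResult:
    """ROC points over probability thresholds with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _positive_proba(forest, X: np.ndarray, positive: str) -> np.ndarray:
    classes = list(forest.classes_)
    if positive not in classes:
        raise ValueError(f"model has no class {positive!r}")
    return forest.predict_proba(X)[:, classes.index(positive)]


def evaluate_roc(
    forest,
    matrix: pd.DataFrame,
    true_labels: pd.Series,
    features: list[str],
    positive: str = "Reactivated",
) -> ROCResult:
    """ROC of predicted reactivation probability on held-out nuclei."""
    true_labels = true_labels.dropna()
    y = (true_labels == positive).to_numpy()
    if y.all() or not y.any():
        raise ValueError("held-out set must contain both classes")
    X = _features(matrix, features, true_labels.index)
    proba = _positive_proba(forest, X, positive)
    fpr, tpr, thr = roc_curve(y, proba)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def predict_primed(
    forest,
    matrix: pd.DataFrame,
    features: list[str],
    nuclei: list[str] | None = None,
    positive: str = "Reactivated",
) -> pd.DataFrame:
    """Reactivation probability and pR/pNR call for single-exposure nuclei.

    A nucleus is predicted-Reactivated (pR) when the forest's most probable
    class is the Reactivated class, else predicted-Not-Reactivated (pNR).
    """
    ids = list(nuclei) if nuclei is not None else list(matrix.columns)
    X = _features(matrix, features, ids)
    proba = _positive_proba(forest, X, positive)
    pred = forest.predict(X)
    return pd.DataFrame({
        "probability_reactivated": proba,
        "predicted_label": np.where(pred == positive, "pR", "pNR"),
    }, index=pd.Index(ids, name="nucleus_id"))


@dataclass
class ReactivityComponent:
    """Leading PC that best separates the reactivity-defined subgroups."""

    scores: pd.Series
    component: int
    t_stat: float
    t_p: float
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    degenerate: bool = False


def reactivity_component(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    probabilities: pd.Series | None = None,
    n_components: int = 10,
    positive_group: str | None = None,
) -> ReactivityComponent:
    """Select the leading principal component separating two subgroups.

    PCA runs on the full transcriptome (centered, unscaled); among the first
    ``n_components`` components the one maximizing the absolute two-sample
    t-statistic between the groups is selected.  If predicted reactivation
    probabilities are supplied, the Pearson correlation between the
    component scores and the probabilities is tested on the shared nuclei.
    """
    from sklearn.decomposition import PCA

    group_labels = group_labels.loc[matrix.columns].dropna()
    levels = sorted(group_labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two subgroups, got {levels}")
    ids_a = group_labels.index[group_labels == levels[0]]
    ids_b = group_labels.index[group_labels == levels[1]]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each subgroup needs at least 2 nuclei")

    X = matrix.to_numpy(dtype=float).T
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pcs = PCA(n_components=k, random_state=0).fit_transform(X)
    pcs_df = pd.DataFrame(pcs, index=matrix.columns)

    best_c, best_t, best_p = 0, 0.0, 1.0
    for c in range(k):
        a = pcs_df.loc[ids_a, c]
        b = pcs_df.loc[ids_b, c]
        if a.std() == 0 and b.std() == 0:
            continue
        res = ttest_ind(a, b)
        if abs(res.statistic) > abs(best_t):
            best_c, best_t, best_p = c, float(res.statistic), float(res.pvalue)

    degenerate = best_t == 0.0
    scores = pcs_df[best_c].rename("reactivity_component")
    # orient so the designated reactivity-side group scores higher
    if positive_group is not None:
        if positive_group not in levels:
            raise ValueError(f"positive_group {positive_group!r} not in {levels}")
        pos_ids = ids_a if positive_group == levels[0] else ids_b
        neg_ids = ids_b if positive_group == levels[0] else ids_a
    else:
        pos_ids, neg_ids = ids_b, ids_a
    if not degenerate and scores.loc[pos_ids].mean() < scores.loc[neg_ids].mean():
        scores = -scores
        best_t = -best_t

    r = p = float("nan")
    if probabilities is not None and not degenerate:
        shared = [i for i in scores.index if i in probabilities.index]
        if len(shared) >= 3:
            res = pearsonr(scores.loc[shared], probabilities.loc[shared])
            r, p = float(res.statistic), float(res.pvalue)
    return ReactivityComponent(
        scores=scores, component=best_c, t_stat=best_t, t_p=best_p,
        pearson_r=r, pearson_p=p, degenerate=degenerate,
    )
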