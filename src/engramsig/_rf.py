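"""Random-forest helpers shared by cluster refinement and reactivity models."""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = ["mean_decrease_gini", "fit_forest", "oob_predictions"]


def mean_decrease_gini(forest: RandomForestClassifier) -> np.ndarray:
    """Per-feature mean decrease in Gini impurity on the count scale.

    Unlike the normalized ``feature_importances_``, this accumulates the raw
    impurity decrease weighted by in-bag sample counts and averages over
    trees, matching the conventional Mean-Decrease-Gini scale on which
    published cutoffs (e.g. > 0.4 or > 1) are stated.
    """
    n_features = forest.n_features_in_
    total = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        left, right = t.children_left[internal], t.children_right[internal]
        w = t.weighted_n_node_samples
        decrease = (
            w[internal] * t.impurity[internal]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        )
        np.add.at(total, t.feature[internal], decrease)
    return total / len(forest.estimators_)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    seed: int,
    oob: bool = False,
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=oob,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def oob_predictions(forest: RandomForestClassifier, y: np.ndarray) -> np.ndarray:
    """Out-of-bag predicted labels; falls back to the true label for samples
    that were in-bag in every tree (essentially impossible at >= 100 trees)."""
    proba = forest.oob_decision_function_
    pred = forest.classes_[np.argmax(proba, axis=1)]
    unseen = np.isnan(proba).any(axis=1) | (proba.sum(axis=1) == 0)
    pred = np.asarray(pred, dtype=object)
    pred[unseen] = y[unseen]
    return pred
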