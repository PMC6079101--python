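"""Predictive-gene selection, forest training and reactivity prediction."""

import numpy as np
import pandas as pd
import pytest

from engramsig import (
    evaluate_roc,
    predict_primed,
    reactivity_component,
    select_predictive_genes,
    train_models,
)
from engramsig.reactivity import batch_association
from conftest import de_table


def _matrix_with_fractions(fractions, n_reactivated=10, expr=3.0):
    """One gene per requested expressed-fraction among Reactivated nuclei."""
    ids = [f"r{i}" for i in range(n_reactivated)]
    rows = {}
    for g, frac in fractions.items():
        k = int(round(frac * n_reactivated))
        rows[g] = [expr] * k + [0.0] * (n_reactivated - k)
    return pd.DataFrame.from_dict(rows, orient="index", columns=ids), ids


class TestSelection:
    def test_expression_fraction_filters(self):
        m, r_ids = _matrix_with_fractions({"keep_up": 0.9, "drop_up": 0.7,
                                           "keep_down": 0.3, "drop_down": 0.6})
        de = de_table(list(m.index), list(m.index))
        de.loc[["keep_down", "drop_down"], "direction"] = "down"
        res = select_predictive_genes(de, m, r_ids)
        assert set(res.genes) == {"keep_up", "keep_down"}
        tab = res.table
        assert (tab.loc[tab["direction"] == "up", "reactivated_fraction"] >= 0.8).all()
        assert (tab.loc[tab["direction"] == "down", "reactivated_fraction"] <= 0.4).all()

    def test_immediate_early_and_batch_genes_excluded(self):
        m, r_ids = _matrix_with_fractions({"good": 1.0, "ieg": 1.0, "batchy": 1.0})
        de = de_table(list(m.index), list(m.index))
        res = select_predictive_genes(
            de, m, r_ids,
            de_1h_vs_hc=de_table(list(m.index), ["ieg"]),
            batch_assoc_genes=["batchy"],
        )
        assert res.genes == ["good"]

    def test_selection_idempotent_and_order_invariant(self):
        m, r_ids = _matrix_with_fractions({"a": 1.0, "b": 0.9, "c": 0.5})
        de = de_table(list(m.index), list(m.index))
        r1 = select_predictive_genes(de, m, r_ids)
        r2 = select_predictive_genes(de.iloc[::-1], m, list(reversed(r_ids)))
        assert r1.genes == r2.genes == ["a", "b"]
        again = select_predictive_genes(de.loc[r1.genes], m, r_ids)
        assert again.genes == r1.genes

    def test_empty_result_is_an_error(self):
        m, r_ids = _matrix_with_fractions({"weak": 0.5})
        de = de_table(list(m.index), list(m.index))
        with pytest.raises(ValueError, match="no predictive genes"):
            select_predictive_genes(de, m, r_ids)


def test_batch_association_flags_planted_batch_gene(rng):
    n = 60
    batches = pd.Series(["b0"] * 30 + ["b1"] * 30,
                        index=[f"n{i}" for i in range(n)])
    X = np.abs(rng.normal(3, 1, size=(40, n)))
    X[0, 30:] += 4.0  # strong batch shift
    m = pd.DataFrame(X, index=[f"g{i}" for i in range(40)], columns=batches.index)
    hits = batch_association(m, batches)
    assert "g0" in hits
    assert len(hits) <= 5


class _ToyForest:
    """Minimal stand-in exposing the forest prediction interface (synthetic)."""

    def __init__(self, proba, classes=("NotReactivated", "Reactivated")):
        self._proba = np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._proba[: len(X)]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class TestROC:
    def _roc(self, probas, labels):
        m = pd.DataFrame(np.zeros((1, len(probas))), index=["g0"],
                         columns=[f"n{i}" for i in range(len(probas))])
        forest = _ToyForest(np.column_stack([1 - np.array(probas), probas]))
        truth = pd.Series(labels, index=m.columns)
        return evaluate_roc(forest, m, truth, ["g0"])

    def test_perfect_separation_gives_unit_auc(self):
        roc = self._roc([0.9, 0.8, 0.3, 0.1],
                        ["Reactivated", "Reactivated",
                         "NotReactivated", "NotReactivated"])
        assert roc.auc == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_points_match_exhaustive_threshold_enumeration(self, rng):
        probas = rng.random(12)
        labels = ["Reactivated" if rng.random() < 0.5 else "NotReactivated"
                  for _ in range(12)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = "Reactivated", "NotReactivated"
        roc = self._roc(probas, labels)
        y = np.array([l == "Reactivated" for l in labels])
        # brute force: every distinct threshold
        pts = set()
        for thr in np.concatenate([[np.inf], np.unique(probas)[::-1]]):
            called = probas >= thr
            tpr = (called & y).sum() / y.sum()
            fpr = (called & ~y).sum() / (~y).sum()
            pts.add((round(fpr, 12), round(tpr, 12)))
        got = {(round(f, 12), round(t, 12)) for f, t in zip(roc.fpr, roc.tpr)}
        assert got <= pts | {(0.0, 0.0)}
        # trapezoid AUC equals probabilistic definition on this toy set
        pos, neg = probas[y], probas[~y]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            self._roc([0.2, 0.4], ["Reactivated", "Reactivated"])


class TestTraining:
    def _cohort(self, rng, n_per_class=20, n_genes=30, sep=4.0):
        cols, labels, blocks = [], [], []
        for cls, shift in (("NewlyActivated", [0, 0]),
                           ("NotReactivated", [0, sep]),
                           ("Reactivated", [sep, sep])):
            block = np.abs(rng.normal(1, 0.5, size=(n_genes, n_per_class)))
            block[: n_genes // 2] += shift[0]   # predictive-like genes
            block[n_genes // 2:] += shift[1]    # late-like genes
            blocks.append(block)
            cols += [f"{cls[:2]}{i}" for i in range(n_per_class)]
            labels += [cls] * n_per_class
        m = pd.DataFrame(np.hstack(blocks),
                         index=[f"g{i}" for i in range(n_genes)], columns=cols)
        return m, pd.Series(labels, index=cols)

    def test_train_test_disjoint_and_errors_low(self, rng):
        m, labels = self._cohort(rng)
        models = train_models(m, labels, list(m.index), n_train_per_class=15,
                              n_trees=300, seed=0)
        assert not set(models.train_ids) & set(models.test_ids)
        assert len(models.train_ids) == 45
        assert all(e <= 0.25 for e in models.per_class_error.values())
        assert set(models.features_pooled) <= set(models.features_pairwise)

    def test_shuffled_labels_give_chance_error(self, rng):
        m, labels = self._cohort(rng)
        errs = []
        for seed in range(5):
            shuffled = pd.Series(
                np.random.default_rng(seed).permutation(labels.to_numpy()),
                index=labels.index)
            models = train_models(m, shuffled, list(m.index),
                                  n_train_per_class=15, n_trees=200, seed=seed,
                                  feature_elimination=False,
                                  gini_pool_cutoff=0.0)
            errs.append(np.mean(list(models.per_class_error.values())))
        assert np.mean(errs) > 0.45

    def test_small_class_is_named(self, rng):
        m, labels = self._cohort(rng, n_per_class=10)
        with pytest.raises(ValueError, match="has 10 nuclei"):
            train_models(m, labels, list(m.index), n_train_per_class=15)

    def test_infinite_pool_cutoff_reports_empty_pool(self, rng):
        m, labels = self._cohort(rng)
        with pytest.raises(ValueError, match="empty"):
            train_models(m, labels, list(m.index), n_train_per_class=15,
                         n_trees=100, gini_pool_cutoff=np.inf,
                         feature_elimination=False)


class TestPrediction:
    def test_training_replica_dominates_baseline(self, rng):
        cohort = TestTraining()
        m, labels = cohort._cohort(rng)
        models = train_models(m, labels, list(m.index), n_train_per_class=15,
                              n_trees=300, seed=1)
        r_train = models.train_ids[-1]  # a Reactivated training nucleus
        assert labels[r_train] == "Reactivated"
        na_id = labels.index[labels == "NewlyActivated"][0]
        probe = m[[r_train, na_id]]
        probe.columns = ["replica", "baseline"]
        pred = predict_primed(models.model_three_way, probe,
                              models.features_pooled)
        assert (pred.loc["replica", "probability_reactivated"]
                >= pred.loc["baseline", "probability_reactivated"])
        assert pred.loc["replica", "predicted_label"] == "pR"

    def test_missing_model_genes_listed(self, rng):
        cohort = TestTraining()
        m, labels = cohort._cohort(rng)
        models = train_models(m, labels, list(m.index), n_train_per_class=15,
                              n_trees=100, seed=1)
        with pytest.raises(ValueError, match="absent"):
            predict_primed(models.model_three_way, m.iloc[1:],
                           models.features_pooled + ["ghost_gene"])


class TestReactivityComponent:
    def test_planted_axis_selected_and_correlated(self, rng):
        n = 40
        X = np.abs(rng.normal(2, 0.5, size=(60, n)))
        signal = np.array([0.0] * 20 + [4.0] * 20)
        X[:15] += signal
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(60)],
                         columns=[f"n{i}" for i in range(n)])
        groups = pd.Series(["lo"] * 20 + ["hi"] * 20, index=m.columns)
        prob = pd.Series(np.clip(signal / 4 + rng.normal(0, 0.1, n), 0, 1),
                         index=m.columns)
        comp = reactivity_component(m, groups, probabilities=prob,
                                    positive_group="hi")
        assert not comp.degenerate
        assert comp.pearson_p < 0.01
        assert comp.pearson_r > 0
        assert comp.scores[groups == "hi"].mean() > comp.scores[groups == "lo"].mean()

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = pd.DataFrame(np.abs(rng.normal(2, 1, size=(50, 30))),
                             index=[f"g{i}" for i in range(50)],
                             columns=[f"n{i}" for i in range(30)])
            groups = pd.Series(["a"] * 15 + ["b"] * 15, index=m.columns)
            prob = pd.Series(rng.random(30), index=m.columns)
            comp = reactivity_component(m, groups, probabilities=prob)
            hits += comp.pearson_p < 0.01
        assert hits <= 1

    def test_identical_groups_flagged_degenerate(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
                         index=["g1", "g2"], columns=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=m.columns)
        comp = reactivity_component(m, groups)
        assert comp.degenerate

    def test_tiny_subgroup_rejected(self, small_matrix):
        groups = pd.Series(["a"] + ["b"] * 11, index=small_matrix.columns)
        with pytest.raises(ValueError, match="at least 2"):
            reactivity_component(small_matrix, groups)
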