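"""Differential-expression statistic, permutation machinery and set overlaps.

The permutation p-values are checked against an independent brute-force
oracle that enumerates every distinct group-label assignment and recomputes
the statistic from first principles.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from engramsig import ROTSParams, overlap_test, rots_test, subsample_deg_counts


def brute_force_pooled_pvalues(X, na):
    """Exhaustive label-enumeration oracle for the fixed statistic
    d = |mean_A - mean_B| / pooled SE, with the null pooled across genes."""
    n = X.shape[1]
    nulls = []
    for ia in combinations(range(n), na):
        ia = list(ia)
        ib = [i for i in range(n) if i not in set(ia)]
        nulls.append(_d(X, ia, ib))
    null = np.concatenate(nulls)
    obs = _d(X, list(range(na)), list(range(na, n)))
    return np.array([(null >= d).sum() / null.size for d in obs])


def _d(X, ia, ib):
    A, B = X[:, ia], X[:, ib]
    na, nb = len(ia), len(ib)
    delta = np.abs(A.mean(1) - B.mean(1))
    sp = ((na - 1) * A.var(1, ddof=1) + (nb - 1) * B.var(1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = delta / se
    return np.where(se == 0, np.where(delta == 0, 0.0, np.inf), d)


def _frame(X, prefix):
    return pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(X.shape[1])])


class TestPermutationOracle:
    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 4)])
    def test_pvalues_match_exhaustive_enumeration(self, rng, na, nb):
        X = rng.normal(2.0, 1.0, size=(15, na + nb))
        X[:5, :na] += 1.5  # a few shifted genes
        X = np.abs(X)
        expected = brute_force_pooled_pvalues(X, na)
        res = rots_test(_frame(X[:, :na], "a"), _frame(X[:, na:], "b"),
                        ROTSParams(alpha1=0.0, alpha2=1.0, seed=1))
        assert res.attrs["exact_null"]
        np.testing.assert_array_equal(res["p_raw"].to_numpy(), expected)

    def test_statistic_matches_hand_computation(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[4.0, 6.0, 8.0]])
        res = rots_test(_frame(a, "a"), _frame(b, "b"),
                        ROTSParams(alpha1=0.0, alpha2=1.0, seed=0))
        delta = abs(2.0 - 6.0)
        sp = (2 * 1.0 + 2 * 4.0) / 4  # pooled variance of {1,2,3} and {4,6,8}
        se = np.sqrt(sp * (2 / 3))
        assert res["d"].iloc[0] == pytest.approx(delta / se, rel=1e-12)
        assert res["mean_a"].iloc[0] == 2.0
        assert res["direction"].iloc[0] == "down"


class TestNullAndInvariants:
    def test_identical_groups_give_zero_statistic(self, small_matrix):
        half = small_matrix.iloc[:, :6]
        dup = half.copy()
        dup.columns = [f"{c}_dup" for c in dup.columns]
        res = rots_test(half, dup, ROTSParams(alpha1=0.0, alpha2=1.0, seed=0))
        assert (res["d"] == 0).all()
        assert (res["p_adj"] >= 0.99).all()

    def test_symmetric_under_group_exchange(self, small_matrix):
        # 4+4 keeps the permutation null exhaustive, so p-values are exactly
        # invariant under group exchange
        a, b = small_matrix.iloc[:, :4], small_matrix.iloc[:, 4:8]
        r1 = rots_test(a, b, ROTSParams(alpha1=0.1, alpha2=1.0, seed=3))
        r2 = rots_test(b, a, ROTSParams(alpha1=0.1, alpha2=1.0, seed=3))
        np.testing.assert_allclose(r1["d"], r2["d"], rtol=1e-12)
        np.testing.assert_array_equal(r1["p_raw"], r2["p_raw"])
        flipped = r2["direction"].map({"up": "down", "down": "up"})
        ties = r1["mean_a"] == r1["mean_b"]
        assert (r1["direction"][~ties] == flipped[~ties]).all()

    def test_bh_adjustment_is_monotone(self, small_matrix):
        res = rots_test(small_matrix.iloc[:, :6], small_matrix.iloc[:, 6:],
                        ROTSParams(alpha1=0.0, alpha2=1.0, seed=0))
        by_raw = res.sort_values("p_raw", kind="stable")
        assert (by_raw["p_adj"].diff().dropna() >= -1e-15).all()
        assert (res["p_adj"] >= res["p_raw"]).all()

    def test_zero_variance_gene_handled(self):
        a = _frame(np.array([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]]), "a")
        b = _frame(np.array([[5.0, 5.0, 5.0], [2.0, 3.0, 4.0]]), "b")
        res = rots_test(a, b, ROTSParams(alpha1=0.0, alpha2=1.0, seed=0))
        assert np.isinf(res["d"].iloc[0])
        assert res["d"].iloc[1] == 0.0

    def test_small_group_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="at least 2"):
            rots_test(small_matrix.iloc[:, :1], small_matrix.iloc[:, 1:])

    def test_alpha_optimization_prefers_planted_signal(self, rng):
        """Tuned statistic detects planted shifts on a small cohort."""
        X = np.abs(rng.normal(3, 1, size=(200, 24)))
        X[:20, :12] += 2.5
        res = rots_test(_frame(X[:, :12], "a"), _frame(X[:, 12:], "b"),
                        ROTSParams(B=100, n_perm=500, seed=7))
        hits = set(res.index[res["p_adj"] < 0.05])
        assert len(hits & {f"g{i}" for i in range(20)}) >= 16


class TestSubsampling:
    def _cohort(self, rng, n=14):
        genes = [f"g{i}" for i in range(150)]
        pops, fos, cols = [], [], []
        X = []
        for pop in ("DG", "CA1"):
            for status in ("pos", "neg"):
                block = np.abs(rng.normal(3, 1, size=(150, n)))
                if pop == "DG" and status == "pos":
                    block[:30] += 2.5
                X.append(block)
                pops += [pop] * n
                fos += [status] * n
                cols += [f"{pop}_{status}_{i}" for i in range(n)]
        m = pd.DataFrame(np.hstack(X), index=genes, columns=cols)
        meta = pd.DataFrame({"population": pops, "fos_protein": fos}, index=cols)
        return m, meta

    def test_responsive_population_dominates(self, rng):
        m, meta = self._cohort(rng)
        table, anova_p = subsample_deg_counts(
            m, meta, n_per_group=10, reps=3, seed=1,
            params=ROTSParams(alpha1=0.1, alpha2=1.0, n_perm=500),
        )
        assert all(d > c for d, c in zip(table.loc["DG", "counts"],
                                         table.loc["CA1", "counts"]))

    def test_single_rep_reports_undefined_sd(self, rng):
        m, meta = self._cohort(rng)
        table, anova_p = subsample_deg_counts(
            m, meta, n_per_group=10, reps=1, seed=1,
            params=ROTSParams(alpha1=0.1, alpha2=1.0, n_perm=200),
        )
        assert np.isnan(table["sd"]).all()
        assert np.isnan(anova_p)

    def test_insufficient_stratum_is_named(self, rng):
        m, meta = self._cohort(rng, n=4)
        with pytest.raises(ValueError, match="too few nuclei"):
            subsample_deg_counts(m, meta, n_per_group=10)


class TestOverlap:
    def test_full_overlap_of_three_in_ten(self):
        u = [f"g{i}" for i in range(10)]
        p = overlap_test(u[:3], u[:3], u)
        assert p == pytest.approx(1 / comb(10, 3), rel=1e-12)

    def test_matches_enumeration_on_small_universe(self, rng):
        u = [f"g{i}" for i in range(9)]
        a = set(rng.choice(u, 4, replace=False))
        b = set(rng.choice(u, 3, replace=False))
        obs = len(a & b)
        count = sum(
            1 for draw in combinations(u, 3) if len(a & set(draw)) >= obs
        )
        assert overlap_test(a, b, u) == pytest.approx(count / comb(9, 3), rel=1e-12)

    def test_trivial_cases(self):
        u = list("abcdef")
        assert overlap_test(["a"], ["b"], u) == pytest.approx(
            float(hypergeom.sf(-1, 6, 1, 1)))  # zero overlap -> P(X>=0)=1
        assert overlap_test(u, u, u) == 1.0
        with pytest.raises(ValueError):
            overlap_test(["a"], ["b"], [])
        with pytest.raises(ValueError):
            overlap_test(["z"], ["a"], u)
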