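from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

import hcdr3 as h


def brute_force_p(x, y):
    """Exact two-sided p by enumerating every labeling of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n - n1) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    dev = abs(u_obs - mu)
    hits = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2 - mu) >= dev - 1e-12
    )
    return hits / comb(n, n1)


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        r = h.mann_whitney_u([1, 2], [3, 4])
        assert r.u_statistic == 0.0

    def test_identical_samples_u_half(self):
        r = h.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.u_statistic == 3 * 3 / 2

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=5),
        st.lists(st.integers(0, 50), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=150)
    def test_exact_p_equals_brute_force(self, xs, ys):
        x, y = np.array(xs, float), np.array(ys, float)
        r = h.mann_whitney_u(x, y)
        if r.method == "exact":
            assert r.p_value == pytest.approx(brute_force_p(x, y))

    def test_agrees_with_scipy_exact_small_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            r = h.mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_agrees_with_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 6, size=40).astype(float)
        y = rng.integers(1, 7, size=35).astype(float)
        r = h.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_and_normal_agree_at_n8(self):
        rng = np.random.default_rng(2)
        from hcdr3.stats import _normal_p

        for _ in range(10):
            x, y = rng.normal(size=8), rng.normal(size=8)
            r = h.mann_whitney_u(x, y)  # n=16 -> normal path
            assert r.method == "normal_approx"
            exact = brute_force_p(np.asarray(x), np.asarray(y))
            assert abs(r.p_value - exact) < 0.02

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=8, unique=True))
    @settings(derandomize=True, max_examples=60)
    def test_invariant_under_monotone_transform(self, vals):
        half = len(vals) // 2
        x, y = vals[:half], vals[half:]
        f = lambda v: [float(t) ** 3 + t for t in v]  # strictly increasing, exact
        r1 = h.mann_whitney_u(x, y)
        r2 = h.mann_whitney_u(f(x), f(y))
        assert r1.u_statistic == r2.u_statistic
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(h.ValidationError):
            h.mann_whitney_u([], [1.0])


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert h.bonferroni([0.01], m=5) == [0.05]
        assert h.bonferroni([0.5], m=5) == [1.0]

    def test_ordering_preserved(self):
        ps = [0.001, 0.02, 0.2, 0.9]
        adj = h.bonferroni(ps, m=4)
        assert adj == sorted(adj)

    def test_small_family_rejected(self):
        with pytest.raises(h.ValidationError):
            h.bonferroni([0.1, 0.2], m=1)
        with pytest.raises(h.ValidationError):
            h.bonferroni([0.1], m=0)


class TestComparePopulations:
    def _two_pop_table(self, shift=0.0, n=300, seed=4):
        wt = h.simulate_repertoire(
            h.SimConfig(seed=seed, clone_sizes=[1] * n, population="preB", genotype="WT")
        )[0]
        ko = h.simulate_repertoire(
            h.SimConfig(seed=seed + 1, clone_sizes=[1] * n, population="preB", genotype="KO")
        )[0]
        df = pd.concat([wt.df, ko.df]).reset_index(drop=True)
        df["sequence_id"] = [f"s{i}" for i in range(len(df))]
        df["population"] = np.where(df.genotype == "WT", "preB_WT", "preB_KO")
        t = h.annotate_properties(h.add_loops(h.RepertoireTable(df)))
        if shift:
            t.df.loc[t.df.population == "preB_KO", "net_charge"] += shift
        return t

    def test_identical_groups_not_significant(self):
        t = self._two_pop_table()
        # same records under both labels
        df = t.df.copy()
        df2 = df.copy()
        df2["sequence_id"] = df2.sequence_id + "_b"
        df["population"], df2["population"] = "A", "B"
        both = h.RepertoireTable(pd.concat([df, df2]).reset_index(drop=True))
        res = h.compare_populations(both, pairs=[("A", "B")])
        assert all(r.p_adjusted == pytest.approx(1.0, abs=1e-9) for r in res)

    def test_injected_charge_shift_significant(self):
        t = self._two_pop_table(shift=0.5, n=500)
        res = h.compare_populations(t, pairs=[("preB_WT", "preB_KO")], properties=("charge",))
        assert res[0].p_adjusted < 0.01

    def test_single_pair_adjustment_is_identity(self):
        t = self._two_pop_table(n=100)
        res = h.compare_populations(t, pairs=[("preB_WT", "preB_KO")])
        assert all(r.p_adjusted == pytest.approx(min(1.0, r.p_value)) for r in res)

    def test_unknown_population_rejected(self):
        t = self._two_pop_table(n=50)
        with pytest.raises(h.ValidationError, match="nosuch"):
            h.compare_populations(t, pairs=[("preB_WT", "nosuch")])


class TestPCA:
    def _profiles(self, seed=0, rows=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(rows, 6)),
            index=[f"pop{i}" for i in range(rows)],
            columns=list("abcdef"),
        )

    def test_rank_one_matrix_pc1_fraction_one(self):
        base = np.array([1.0, -2.0, 0.5, 3.0, 1.5, -1.0])
        X = pd.DataFrame(np.outer([0.0, 1.0, 2.0, 4.0], base), columns=list("abcdef"))
        res = h.pca_profiles(X)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        res = h.pca_profiles(self._profiles())
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.variance_fraction >= 0).all()

    def test_reconstruction(self):
        X = self._profiles(seed=3)
        res = h.pca_profiles(X)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(rec, X - X.mean(axis=0), atol=1e-9)

    def test_loadings_orthonormal(self):
        res = h.pca_profiles(self._profiles(seed=7))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        res = h.pca_profiles(self._profiles(seed=9))
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_centring_invariance(self):
        X = self._profiles(seed=11)
        res1 = h.pca_profiles(X)
        res2 = h.pca_profiles(X + np.array([10.0, -3, 0, 5, 1, 2]))
        np.testing.assert_allclose(
            res1.scores.to_numpy(), res2.scores.to_numpy(), atol=1e-9
        )

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        X = self._profiles(seed=13)
        res = h.pca_profiles(X)
        sk = PCA().fit(X.to_numpy())
        np.testing.assert_allclose(
            res.variance_fraction[: len(sk.explained_variance_ratio_)],
            sk.explained_variance_ratio_,
            atol=1e-9,
        )
        for j in range(min(3, res.loadings.shape[1])):
            a = res.loadings.iloc[:, j].to_numpy()
            b = sk.components_[j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_single_row_rejected(self):
        with pytest.raises(h.ValidationError):
            h.pca_profiles(self._profiles(rows=1))

    def test_zero_variance_warns_and_zeroes(self):
        X = pd.DataFrame(np.ones((4, 6)), columns=list("abcdef"))
        with pytest.warns(UserWarning):
            res = h.pca_profiles(X)
        assert (res.variance_fraction == 0).all()
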