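import numpy as np
import pandas as pd
import pytest

from nichepart import (
    alr_transform,
    bh_fdr,
    build_r_table,
    fourth_corner_stat,
    fourth_corner_test,
    rlq,
)


def pearson_on_inflated(L, x, q):
    """Independent oracle: expand L to one record per unit of count and
    take the ordinary Pearson correlation of the (x, q) pairs."""
    xs, qs = [], []
    L = np.asarray(L)
    for i in range(L.shape[0]):
        for j in range(L.shape[1]):
            for _ in range(int(L[i, j])):
                xs.append(x[i])
                qs.append(q[j])
    return np.corrcoef(xs, qs)[0, 1]


def _random_lrq(rng, n=8, m=6, p=2, t=2):
    L = pd.DataFrame(
        rng.integers(0, 4, size=(n, m)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(m)],
    )
    L.iloc[0, 0] += 1  # guarantee a non-empty table
    R = pd.DataFrame(
        rng.normal(size=(n, p)), index=L.index,
        columns=[f"x{k}" for k in range(p)],
    )
    Q = pd.DataFrame(
        rng.normal(size=(m, t)), index=L.columns,
        columns=[f"q{k}" for k in range(t)],
    )
    return L, R, Q


class TestAlr:
    def test_hand_value(self):
        h = pd.DataFrame([[0.25, 0.25, 0.5]], columns=["a", "b", "c"],
                         index=["col1"])
        out = alr_transform(h, ref="c", pseudocount=0.0)
        assert out.loc["col1", "a"] == pytest.approx(np.log(0.5))
        assert out.loc["col1", "b"] == pytest.approx(np.log(0.5))
        assert list(out.columns) == ["a", "b"]

    def test_equal_composition_maps_to_zero(self):
        h = pd.DataFrame([[0.25] * 4], columns=list("abcd"), index=["c"])
        out = alr_transform(h, ref="d", pseudocount=0.0)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        raw = rng.random((3, 5)) + 0.05
        h1 = pd.DataFrame(raw / raw.sum(1, keepdims=True),
                          columns=list("abcde"))
        scaled = raw * np.array([[2.0], [0.5], [7.0]])
        h2 = pd.DataFrame(scaled / scaled.sum(1, keepdims=True),
                          columns=list("abcde"))
        pd.testing.assert_frame_equal(
            alr_transform(h1, ref="e", pseudocount=0.0),
            alr_transform(h2, ref="e", pseudocount=0.0),
        )

    def test_default_pseudocount_handles_zeros(self):
        h = pd.DataFrame([[0.0, 0.4, 0.6]], columns=list("abc"))
        out = alr_transform(h, ref="c")
        assert np.isfinite(out.to_numpy()).all()

    def test_missing_reference_rejected(self):
        h = pd.DataFrame([[0.5, 0.5]], columns=["a", "b"])
        with pytest.raises(KeyError, match="nope"):
            alr_transform(h, ref="nope")


class TestFourthCornerStat:
    def test_perfect_diagonal_association(self):
        L = [[1, 0], [0, 1]]
        assert fourth_corner_stat(L, [0, 1], [0, 1]) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        L = [[1, 1], [1, 1]]
        assert fourth_corner_stat(L, [0, 1], [0, 1]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_antisymmetry_in_trait(self):
        rng = np.random.default_rng(1)
        L = rng.integers(0, 5, size=(5, 4))
        L[0, 0] += 1
        x, q = rng.normal(size=5), rng.normal(size=4)
        r = fourth_corner_stat(L, x, q)
        assert fourth_corner_stat(L, x, -q) == pytest.approx(-r)

    def test_matches_inflated_table_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            L = rng.integers(0, 3, size=(5, 4))
            if L.sum() == 0:
                continue
            x, q = rng.normal(size=5), rng.normal(size=4)
            # the oracle needs both variables to vary within the support
            try:
                ours = fourth_corner_stat(L, x, q)
            except ValueError:
                continue
            ref = pearson_on_inflated(L, x, q)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_degenerate_variable_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fourth_corner_stat([[1, 1], [1, 1]], [1.0, 1.0], [0, 1])


class TestFourthCornerTest:
    def test_model6_is_cellwise_max(self):
        rng = np.random.default_rng(3)
        L, R, Q = _random_lrq(rng)
        res = fourth_corner_test(L, R, Q, n_perm=99, seed=0)
        assert (
            res.p_model6.to_numpy()
            == np.maximum(res.p_model2.to_numpy(), res.p_model4.to_numpy())
        ).all()
        # hence model-6 rejection implies rejection under both models
        alpha = 0.05
        reject6 = res.p_model6.to_numpy() <= alpha
        assert (res.p_model2.to_numpy()[reject6] <= alpha).all()
        assert (res.p_model4.to_numpy()[reject6] <= alpha).all()

    def test_adjusted_p_dominates_p6(self):
        rng = np.random.default_rng(4)
        L, R, Q = _random_lrq(rng, p=3, t=3)
        res = fourth_corner_test(L, R, Q, n_perm=99, seed=1)
        assert (
            res.p_adjusted.to_numpy() >= res.p_model6.to_numpy() - 1e-12
        ).all()
        assert ((res.stat.to_numpy() >= -1 - 1e-9)
                & (res.stat.to_numpy() <= 1 + 1e-9)).all()

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        L, R, Q = _random_lrq(rng)
        r1 = fourth_corner_test(L, R, Q, n_perm=99, seed=42)
        r2 = fourth_corner_test(L, R, Q, n_perm=99, seed=42)
        pd.testing.assert_frame_equal(r1.p_model6, r2.p_model6)

    def test_stat_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        L, R, Q = _random_lrq(rng)
        res1 = fourth_corner_test(L, R, Q, n_perm=9, seed=0)
        perm = rng.permutation(len(L))
        res2 = fourth_corner_test(
            L.iloc[perm], R.iloc[perm], Q, n_perm=9, seed=0
        )
        pd.testing.assert_frame_equal(res1.stat, res2.stat)

    def test_dimension_mismatch_named(self):
        rng = np.random.default_rng(7)
        L, R, Q = _random_lrq(rng)
        with pytest.raises(ValueError, match="R_table"):
            fourth_corner_test(L, R.iloc[:-1], Q, n_perm=9)
        with pytest.raises(ValueError, match="Q_table"):
            fourth_corner_test(L, R, Q.iloc[:-1], n_perm=9)


class TestRlq:
    def test_single_pair_eigenvalue_equals_squared_correlation(self):
        rng = np.random.default_rng(8)
        L, R, Q = _random_lrq(rng, p=1, t=1)
        res = rlq(R, L, Q)
        r = fourth_corner_stat(L, R.iloc[:, 0], Q.iloc[:, 0])
        assert res.eigenvalues[0] == pytest.approx(r**2, abs=1e-12)

    def test_eigenvalues_sum_to_total_coinertia(self):
        rng = np.random.default_rng(9)
        L, R, Q = _random_lrq(rng, p=3, t=4)
        res = rlq(R, L, Q)
        assert res.eigenvalues.sum() == pytest.approx(
            res.total_coinertia, abs=1e-9
        )
        assert (res.eigenvalues >= -1e-12).all()

    def test_invariant_to_prey_permutation(self):
        rng = np.random.default_rng(10)
        L, R, Q = _random_lrq(rng, p=2, t=3)
        res1 = rlq(R, L, Q)
        perm = rng.permutation(L.shape[1])
        res2 = rlq(R, L.iloc[:, perm], Q.iloc[perm])
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-12)

    def test_structureless_table_has_zero_coinertia(self):
        # L rows proportional to a fixed prey profile: the chi-square
        # residuals vanish, so every eigenvalue must be ~0
        base = np.array([4, 2, 1, 1], dtype=float)
        L = pd.DataFrame(
            np.outer([1, 2, 3], base),
            index=["s0", "s1", "s2"],
            columns=[f"m{j}" for j in range(4)],
        )
        rng = np.random.default_rng(11)
        R = pd.DataFrame(rng.normal(size=(3, 2)), index=L.index)
        Q = pd.DataFrame(rng.normal(size=(4, 2)), index=L.columns)
        res = rlq(R, L, Q)
        assert (np.abs(res.eigenvalues) < 1e-10).all()

    def test_first_eigenvalue_bounds_any_pair_covariance(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            L, R, Q = _random_lrq(rng, p=3, t=3)
            res = rlq(R, L, Q)
            for a in R.columns:
                for b in Q.columns:
                    r = fourth_corner_stat(L, R[a], Q[b])
                    assert res.eigenvalues[0] >= r**2 - 1e-10

    def test_empty_rows_dropped_with_warning(self):
        rng = np.random.default_rng(13)
        L, R, Q = _random_lrq(rng)
        L.iloc[1] = 0
        with pytest.warns(UserWarning, match="empty"):
            res = rlq(R, L, Q)
        assert "s1" not in res.sample_scores.index


class TestBhFdr:
    def test_hand_example(self):
        adj = bh_fdr(np.array([0.005, 0.01, 0.03, 0.04]))
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(14)
        p = rng.random(40)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1.0).all() and (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestBuildRTable:
    def test_species_indicators_and_alr_columns(self, worked):
        meta, habitat = worked["table"].meta, worked["habitat"]
        R = build_r_table(meta, habitat)
        assert list(R.columns[:2]) == ["auritus", "austriacus"]
        assert R.shape == (6, 2 + 5)  # 2 species present + 5 ALR predictors
        assert R.loc["A1", "auritus"] == 1.0
        assert R.loc["B1", "auritus"] == 0.0

    def test_raw_proportions_variant(self, worked):
        meta, habitat = worked["table"].meta, worked["habitat"]
        R = build_r_table(meta, habitat, use_alr=False)
        assert R.shape == (6, 2 + 6)
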