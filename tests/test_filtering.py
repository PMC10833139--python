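import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvintegrate import (
    Outcome,
    ValidationError,
    adjust_pvalues,
    apply_filter,
    preprocess,
    supervised_filter,
    unsupervised_filter,
)


class TestPreprocess:
    def test_center(self):
        X = np.array([[1.0], [2.0], [3.0]])
        out, _ = preprocess(X, center=True)
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1])

    def test_log2_plus_one(self):
        X = np.array([[0.0], [1.0], [3.0]])
        out, _ = preprocess(X, log2=True)
        np.testing.assert_allclose(out[:, 0], [0, 1, 2])

    def test_normalize_equals_center_scale(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        a, _ = preprocess(X, normalize=True)
        b, _ = preprocess(X, center=True, scale=True)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(a.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_train_params_not_reestimated(self):
        rng = np.random.default_rng(1)
        Xtr = rng.normal(size=(30, 3))
        Xte = rng.normal(loc=5.0, size=(10, 3))
        _, rec = preprocess(Xtr, normalize=True)
        out, rec2 = preprocess(Xte, train_params=rec)
        assert rec2 is rec
        # test means reflect the location shift, not zero
        assert np.all(np.abs(out.mean(axis=0)) > 1.0)

    def test_log2_domain_error(self):
        with pytest.raises(ValidationError, match="log2"):
            preprocess(np.array([[-2.0]]), log2=True)

    def test_zero_variance_error_and_drop(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValidationError, match="zero-variance"):
            preprocess(X, scale=True)
        with pytest.warns(UserWarning):
            out, _ = preprocess(X, scale=True, on_zero_variance="drop")
        assert out.shape == X.shape  # column kept, left unscaled


class TestAdjustPvalues:
    def test_bh_hand_case(self):
        np.testing.assert_allclose(
            adjust_pvalues(np.array([0.01, 0.02, 0.04]), "BH"),
            [0.03, 0.03, 0.04])

    def test_single_p(self):
        for method in ("BH", "bonferroni", "none"):
            np.testing.assert_allclose(adjust_pvalues(np.array([0.5]), method), [0.5])

    def test_bh_order_equivariant(self):
        p = np.array([0.04, 0.02, 0.01])
        out = adjust_pvalues(p, "BH")
        np.testing.assert_allclose(np.sort(out), [0.03, 0.03, 0.04])
        # same multiset as the sorted input case, mapped back by rank
        np.testing.assert_allclose(out, [0.04, 0.03, 0.03])

    def test_bonferroni(self):
        np.testing.assert_allclose(
            adjust_pvalues(np.array([0.01, 0.4, 0.9]), "bonferroni"),
            [0.03, 1.0, 1.0])

    def test_invalid_p(self):
        with pytest.raises(ValidationError):
            adjust_pvalues(np.array([0.5, 1.5]), "BH")

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(adjust_pvalues(p, "BH"),
                                   multipletests(p, method="fdr_bh")[1])
        np.testing.assert_allclose(adjust_pvalues(p, "bonferroni"),
                                   multipletests(p, method="bonferroni")[1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw(self, plist):
        p = np.array(plist)
        for method in ("BH", "bonferroni"):
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1 + 1e-12)


class TestSupervisedFilter:
    def test_perfect_association_kept(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        X = np.column_stack([y, rng.normal(size=50)])
        res = supervised_filter(X, ["f1", "f2"], Outcome("continuous", values=y),
                                method="linear", padjust=False, alpha=0.05)
        assert res.table.loc[0, "p_value"] < 1e-20
        assert bool(res.table.loc[0, "keep"])

    def test_constant_feature_ttest(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        res = supervised_filter(X, ["const", "noise"],
                                Outcome("binary", values=y), method="ttest")
        assert res.table.loc[0, "statistic"] == 0.0
        assert res.table.loc[0, "p_value"] == 1.0
        assert not bool(res.table.loc[0, "keep"])

    def test_ttest_effect_is_group_mean_difference(self):
        y = np.array([0] * 5 + [1] * 5)
        X = np.concatenate([np.zeros(5), np.full(5, 3.0)])[:, None]
        X = X + np.random.default_rng(0).normal(scale=0.01, size=(10, 1))
        res = supervised_filter(X, ["f"], Outcome("binary", values=y), method="ttest")
        assert res.table.loc[0, "effect"] == pytest.approx(3.0, abs=0.05)

    def test_logistic_separation_flagged(self):
        y = np.array([0] * 10 + [1] * 10)
        sep = np.concatenate([np.zeros(10), np.ones(10)])  # perfect separation
        rng = np.random.default_rng(5)
        X = np.column_stack([sep, rng.normal(size=20)])
        with pytest.warns(UserWarning, match="logistic"):
            res = supervised_filter(X, ["sep", "noise"],
                                    Outcome("binary", values=y), method="logistic")
        assert np.isnan(res.table.loc[0, "p_value"])
        assert not bool(res.table.loc[0, "keep"])

    def test_kw_multigroup(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1, 2], 15)
        X = np.column_stack([y + rng.normal(scale=0.3, size=45),
                             rng.normal(size=45)])
        res = supervised_filter(X, ["sig", "noise"],
                                Outcome("multiclass", values=y), method="kw",
                                padjust=False)
        assert res.table.loc[0, "p_value"] < 1e-4
        assert res.table.loc[1, "p_value"] > 0.001

    def test_family_outcome_mismatch(self):
        y = np.random.default_rng(0).normal(size=20)
        X = np.random.default_rng(1).normal(size=(20, 2))
        with pytest.raises(ValidationError):
            supervised_filter(X, ["a", "b"], Outcome("continuous", values=y),
                              method="logistic")

    def test_null_bh_keeps_few(self):
        # global null: 40 pure-noise features vs random binary outcome
        rng = np.random.default_rng(7)
        kept = []
        for _ in range(50):
            X = rng.normal(size=(40, 40))
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            res = supervised_filter(X, [f"f{j}" for j in range(40)],
                                    Outcome("binary", values=y), method="ttest",
                                    padjust=True, adjmethod="BH", alpha=0.05)
            kept.append(res.table["keep"].sum())
        assert np.mean(kept) < 2.5

    def test_ttest_kw_rank_agreement(self):
        # strongly-signaled data: both tests should rank features similarly
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        n, p = 60, 30
        y = np.array([0] * 30 + [1] * 30)
        effects = np.linspace(0, 2.0, p)
        X = rng.normal(size=(n, p)) + np.outer(y, effects)
        names = [f"f{j}" for j in range(p)]
        out = Outcome("binary", values=y)
        rt = supervised_filter(X, names, out, method="ttest")
        rk = supervised_filter(X, names, out, method="kw")
        lt = -np.log10(np.clip(rt.table["p_value"], 1e-300, None))
        lk = -np.log10(np.clip(rk.table["p_value"], 1e-300, None))
        assert spearmanr(lt, lk).statistic > 0.8


class TestUnsupervisedFilter:
    def test_variance_top_third(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3)) * np.sqrt([1.0, 2.0, 3.0])
        res = unsupervised_filter(X, ["f1", "f2", "f3"], "variance",
                                  keep_fraction=1 / 3)
        assert res.kept_features == ["f3"]

    def test_keep_all(self):
        X = np.random.default_rng(10).normal(size=(20, 5))
        names = [f"f{j}" for j in range(5)]
        res = unsupervised_filter(X, names, "variance", keep_fraction=1.0)
        assert res.kept_features == names

    def test_iqr_matches_quantile_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(37, 50)) * rng.uniform(0.1, 5.0, size=50)
        res = unsupervised_filter(X, [f"f{j}" for j in range(50)], "iqr",
                                  keep_fraction=0.3)
        # brute-force type-7 quantile oracle
        oracle = np.array([
            np.quantile(X[:, j], 0.75) - np.quantile(X[:, j], 0.25)
            for j in range(50)
        ])
        np.testing.assert_allclose(res.table["statistic"], oracle, atol=1e-12)
        n_keep = int(np.ceil(0.3 * 50))
        expect = set(np.argsort(-oracle, kind="stable")[:n_keep])
        got = {int(name[1:]) for name in res.kept_features}
        assert got == expect

    def test_bad_fraction(self):
        with pytest.raises(ValidationError):
            unsupervised_filter(np.ones((5, 2)), ["a", "b"], "variance",
                                keep_fraction=0.0)


class TestApplyFilter:
    def _result(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3)) * np.sqrt([3.0, 2.0, 1.0])
        return unsupervised_filter(X, ["f1", "f2", "f3"], "variance",
                                   keep_fraction=2 / 3)

    def test_restricts_to_kept(self):
        res = self._result()
        assert res.kept_features == ["f1", "f2"]
        Xte = np.arange(12.0).reshape(4, 3)
        out, names = apply_filter(Xte, ["f1", "f2", "f3"], res)
        assert names == ["f1", "f2"]
        np.testing.assert_array_equal(out, Xte[:, :2])

    def test_extras_dropped_silently(self):
        res = self._result()
        Xte = np.arange(16.0).reshape(4, 4)
        out, names = apply_filter(Xte, ["extra", "f2", "f1", "more"], res)
        assert names == ["f1", "f2"]
        np.testing.assert_array_equal(out, Xte[:, [2, 1]])

    def test_missing_kept_feature_named(self):
        res = self._result()
        with pytest.raises(ValidationError, match="f2"):
            apply_filter(np.ones((2, 2)), ["f1", "f3"], res)

    def test_keep_all_then_apply_is_identity(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 4))
        names = [f"f{j}" for j in range(4)]
        res = unsupervised_filter(X, names, "variance", keep_fraction=1.0)
        out, out_names = apply_filter(X, names, res)
        assert out_names == names
        np.testing.assert_array_equal(out, X)
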