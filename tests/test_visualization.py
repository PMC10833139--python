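import numpy as np
import pandas as pd
import pytest

from mvintegrate import ValidationError
from mvintegrate.filtering import FilterResult
from mvintegrate.selpcca import SelpccaModel
from mvintegrate import visualization as viz


def make_selpcca(hatalpha, hatbeta, names1=None, names2=None):
    """Hand-built SelpccaModel for table tests."""
    hatalpha = np.asarray(hatalpha, float)
    hatbeta = np.asarray(hatbeta, float)
    p1, K = hatalpha.shape
    p2 = hatbeta.shape[0]
    return SelpccaModel(
        hatalpha=hatalpha, hatbeta=hatbeta,
        opt_tau=np.zeros((2, K)), maxcorr=np.zeros(K),
        train_scores_u=np.zeros((1, K)), train_scores_v=np.zeros((1, K)),
        feature_names=[names1 or [f"a{j}" for j in range(p1)],
                       names2 or [f"b{j}" for j in range(p2)]],
        view_names=["view1", "view2"], ncancorr=K,
        nonzero=np.vstack([(hatalpha != 0).sum(0), (hatbeta != 0).sum(0)]))


def unit(v):
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    return v / n if n else v


def filter_result(p_adj, effect=None, method="ttest"):
    m = len(p_adj)
    table = pd.DataFrame({
        "name": [f"f{j}" for j in range(m)],
        "statistic": np.zeros(m),
        "effect": effect if effect is not None else np.zeros(m),
        "p_value": p_adj,
        "p_adjusted": p_adj,
        "keep": np.asarray(p_adj) <= 0.05,
    })
    return FilterResult(view_name="v", method=method, table=table, alpha=0.05)


class TestVolcano:
    def test_neg_log10_values(self):
        t = viz.volcano_table(filter_result([0.01, 1.0]))
        assert t.loc[0, "neg_log10_adj_p"] == pytest.approx(2.0)
        assert t.loc[1, "neg_log10_adj_p"] == pytest.approx(0.0)

    def test_zero_p_capped(self):
        t = viz.volcano_table(filter_result([0.0]))
        assert t.loc[0, "neg_log10_adj_p"] == 300.0
        assert bool(t.loc[0, "capped"])

    def test_unsupervised_rejected(self):
        res = filter_result([0.5], method="variance")
        with pytest.raises(ValidationError, match="supervised"):
            viz.volcano_table(res)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, size=(30, 5)),
                   rng.normal(10, 1, size=(30, 5))])
    labels = np.array([0] * 30 + [1] * 30)
    return X, labels


class TestUmap:
    def test_shape_and_determinism(self, blobs):
        X, labels = blobs
        t1 = viz.umap_table(X, labels, seed=7)
        t2 = viz.umap_table(X, labels, seed=7)
        assert len(t1) == 60
        assert {"dim1", "dim2"} <= set(t1.columns)
        pd.testing.assert_frame_equal(t1, t2)

    def test_separated_blobs_silhouette(self, blobs):
        from sklearn.metrics import silhouette_score

        X, labels = blobs
        t = viz.umap_table(X, labels, seed=7)
        score = silhouette_score(t[["dim1", "dim2"]].to_numpy(), labels)
        assert score > 0.5

    def test_too_few_samples(self):
        with pytest.raises(ValidationError, match="10"):
            viz.umap_table(np.zeros((5, 3)))


class TestImportance:
    def test_abs_ordering(self):
        m = make_selpcca(np.array([unit([0.9, -0.95, 0.1])]).T,
                         np.array([unit([1.0, 0.0])]).T)
        t = viz.importance_table(m, view=0, component=0, top_n=2)
        # normalization preserves relative magnitudes
        assert t["name"].tolist() == ["a1", "a0"]
        assert t.loc[0, "loading"] < 0

    def test_top_n_exceeds_p(self):
        m = make_selpcca(np.array([unit([0.5, 0.5, 0.0])]).T,
                         np.array([unit([1.0])]).T)
        t = viz.importance_table(m, view=0, top_n=99)
        assert len(t) == 2  # only nonzero variables

    def test_all_zero_warns_empty(self):
        m = make_selpcca(np.zeros((3, 1)), np.array([unit([1.0])]).T)
        with pytest.warns(UserWarning, match="zero"):
            t = viz.importance_table(m, view=0)
        assert t.empty

    def test_component_out_of_range(self):
        m = make_selpcca(np.array([unit([1.0])]).T, np.array([unit([1.0])]).T)
        with pytest.raises(ValidationError, match="component"):
            viz.importance_table(m, component=5)


class TestDiscriminantAndCorrelation:
    def test_q1_single_score_column(self, sida_model, sida_small):
        data, _ = sida_small
        tabs = viz.discriminant_table(sida_model, data.views,
                                      np.asarray(data.outcome.values))
        for t in tabs.values():
            assert "score_1" in t.columns
            assert "score_2" not in t.columns

    def test_separation_on_strong_signal(self, sida_model, sida_small):
        data, _ = sida_small
        tabs = viz.discriminant_table(sida_model, data.views,
                                      np.asarray(data.outcome.values))
        t = list(tabs.values())[0]
        g1 = t.loc[t["class"] == 1, "score_1"]
        g2 = t.loc[t["class"] == 2, "score_1"]
        assert abs(g1.mean() - g2.mean()) > 2 * max(g1.std(), g2.std())

    def test_unlabeled_rejected(self, sida_model, sida_small):
        data, _ = sida_small
        with pytest.raises(ValidationError):
            viz.discriminant_table(sida_model, data.views, None)

    def test_correlation_identical_views(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        m = make_selpcca(np.array([unit([1.0, 0, 0])]).T,
                         np.array([unit([1.0, 0, 0])]).T)
        tabs = viz.correlation_table(m, [X, X], np.zeros(40))
        t = list(tabs.values())[0]
        assert t.attrs["pearson_r"] == pytest.approx(1.0)

    def test_annotation_self_consistent(self, selpcca_model, selp_small):
        data, _ = selp_small
        tabs = viz.correlation_table(selpcca_model, data.views,
                                     np.asarray(data.outcome.values))
        t = list(tabs.values())[0]
        r = np.corrcoef(t["score_view_1"], t["score_view_2"])[0, 1]
        assert t.attrs["pearson_r"] == pytest.approx(r, abs=1e-12)


class TestRelevanceNetwork:
    def _model(self):
        return make_selpcca(np.array([unit([1.0, 0.5]), ]).T,
                            np.array([unit([1.0, 0.5]), ]).T)

    def test_identical_column_solid_unit_edge(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X1 = np.column_stack([x, rng.normal(size=50)])
        X2 = np.column_stack([x, rng.normal(size=50)])
        g = viz.relevance_network(self._model(), X1, X2, cutoff=0.9)
        edge = g.edges[(g.edges.node1 == "a0") & (g.edges.node2 == "b0")]
        assert edge["weight"].iloc[0] == pytest.approx(1.0)
        assert edge["sign"].iloc[0] == "solid"

    def test_negated_column_dashed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X1 = np.column_stack([x, rng.normal(size=50)])
        X2 = np.column_stack([-x, rng.normal(size=50)])
        g = viz.relevance_network(self._model(), X1, X2, cutoff=0.9)
        edge = g.edges[(g.edges.node1 == "a0") & (g.edges.node2 == "b0")]
        assert edge["weight"].iloc[0] == pytest.approx(-1.0)
        assert edge["sign"].iloc[0] == "dashed"

    def test_cutoff_semantics(self):
        # correlations approx (0.6, 0.5); cutoff 0.58 keeps exactly one edge
        rng = np.random.default_rng(4)
        n = 100000
        x = rng.normal(size=n)
        y06 = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        y05 = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        X1 = np.column_stack([x, rng.normal(size=n)])
        X2 = np.column_stack([y06, y05])
        g = viz.relevance_network(self._model(), X1, X2, cutoff=0.58)
        assert len(g.edges) == 1

    def test_cutoff_monotone(self, selpcca_model, selp_small):
        data, _ = selp_small
        sizes = []
        for cutoff in (0.2, 0.5, 0.8):
            g = viz.relevance_network(selpcca_model, *data.views, cutoff=cutoff)
            sizes.append(len(g.edges))
        assert sizes == sorted(sizes, reverse=True)

    def test_isolated_nodes_dropped(self, selpcca_model, selp_small):
        data, _ = selp_small
        g = viz.relevance_network(selpcca_model, *data.views, cutoff=0.5)
        used = set(g.edges["node1"]) | set(g.edges["node2"])
        assert set(g.nodes["name"]) == used

    def test_invalid_cutoff(self):
        with pytest.raises(ValidationError):
            viz.relevance_network(self._model(), np.ones((5, 2)), np.ones((5, 2)),
                                  cutoff=1.5)


class TestLoadingsAndBiplots:
    def test_loadings_on_axis(self):
        a = np.column_stack([unit([1.0, 0, 0]), unit([0, 1.0, 0])])
        m = make_selpcca(a, a.copy())
        t = viz.loadings_table(m, view=0)
        row = t[t["name"] == "a0"].iloc[0]
        assert row["loading_comp1"] == pytest.approx(1.0)
        assert row["loading_comp2"] == pytest.approx(0.0)

    def test_unit_disk_and_zero_excluded(self):
        a = np.column_stack([unit([0.6, 0.8, 0.0]), unit([0.8, -0.6, 0.0])])
        m = make_selpcca(a, a.copy())
        t = viz.loadings_table(m, view=0)
        assert "a2" not in t["name"].tolist()
        r = np.hypot(t["loading_comp1"], t["loading_comp2"])
        assert np.all(r <= 1 + 1e-9)

    def test_biplot_within_score_variable(self, selp_small):
        data, _ = selp_small
        X1 = np.asarray(data.views[0])
        # model whose score_1 is exactly feature a0
        a = np.zeros((30, 2))
        a[0, 0] = 1.0
        a[1, 1] = 1.0
        m = make_selpcca(a, a.copy())
        samples, arrows = viz.biplot_within(m, X1,
                                            np.asarray(data.outcome.values), view=0)
        arrow0 = arrows[arrows["name"] == "a0"].iloc[0]
        assert arrow0["a1"] == pytest.approx(1.0, abs=1e-10)
        assert len(arrows) <= 10
        # each coordinate is a correlation; bounded componentwise (the axes
        # themselves may be correlated, so the Euclidean length may exceed 1)
        assert np.all(arrows["a1"].abs() <= 1 + 1e-9)
        assert np.all(arrows["a2"].abs() <= 1 + 1e-9)

    def test_biplot_between_consistency(self, selpcca_model, selp_small):
        data, _ = selp_small
        labels = np.asarray(data.outcome.values)
        _, within = viz.biplot_within(selpcca_model, data.views[0], labels, view=0)
        _, between = viz.biplot_between(selpcca_model, *data.views, labels)
        b1 = between[between["view"] == 1].set_index("name")
        w = within.set_index("name")
        shared = w.index.intersection(b1.index)
        assert len(shared) > 0
        np.testing.assert_allclose(w.loc[shared, ["a1", "a2"]],
                                   b1.loc[shared, ["a1", "a2"]], atol=1e-12)
        assert set(between["style"]) <= {"solid", "dashed"}


class TestRendering:
    def test_renderers_write_files(self, tmp_path, selpcca_model, selp_small):
        data, _ = selp_small
        labels = np.asarray(data.outcome.values)
        vt = viz.volcano_table(filter_result([0.01, 0.2, 0.5],
                                             effect=[1.0, -1.0, 0.0]))
        viz.render_volcano(vt, tmp_path / "v.png")
        imp = viz.importance_table(selpcca_model, view=0)
        viz.render_importance(imp, tmp_path / "i.png")
        g = viz.relevance_network(selpcca_model, *data.views, cutoff=0.5)
        viz.render_network(g, tmp_path / "n.png")
        samples, arrows = viz.biplot_within(selpcca_model, data.views[0],
                                            labels, view=0)
        viz.render_biplot(samples, arrows, tmp_path / "b.png")
        for name in ("v", "i", "n", "b"):
            assert (tmp_path / f"{name}.png").stat().st_size > 0
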