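"""Plot-table computation and thin matplotlib rendering.

Every plot family is computed first as a plain table (pandas DataFrame) or a
:class:`RelevanceGraph`; rendering functions are pure consumers of those
tables so tests target the numbers, not pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .filtering import FilterResult
from .selpcca import SelpccaModel
from .sida import SidaModel

NEG_LOG10_CAP = 300.0


@dataclass
class RelevanceGraph:
    """Bipartite signed-correlation network between two views' selected variables."""

    nodes: pd.DataFrame  # columns: view, name, shape (circle/rectangle)
    edges: pd.DataFrame  # columns: node1, node2, weight, sign (solid/dashed)
    cutoff: float


def volcano_table(result: FilterResult) -> pd.DataFrame:
    """(name, effect, neg_log10_adj_p, significant) from a supervised filter."""
    if result.method not in ("linear", "logistic", "ttest", "kw"):
        raise ValidationError("volcano plots require a supervised FilterResult")
    t = result.table
    p = t["p_adjusted"].to_numpy(dtype=float)
    if np.all(np.isnan(p)):
        p = t["p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        y = -np.log10(p)
    capped = np.isinf(y)
    y = np.where(capped, NEG_LOG10_CAP, np.minimum(y, NEG_LOG10_CAP))
    return pd.DataFrame({
        "name": t["name"],
        "effect": t["effect"],
        "neg_log10_adj_p": y,
        "capped": capped | (y >= NEG_LOG10_CAP),
        "significant": t["keep"],
    })


def umap_table(
    X: np.ndarray,
    labels: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """2-D UMAP embedding table; delegates to umap-learn with a fixed seed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValidationError("UMAP requires at least 10 samples")
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, n - 2),
            random_state=seed,
        ).fit_transform(X)
    out = pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None else [str(i) for i in range(n)],
        "dim1": emb[:, 0],
        "dim2": emb[:, 1],
    })
    out["label"] = labels if labels is not None else ""
    return out


def _view_loadings(model, view: int) -> tuple[np.ndarray, list[str]]:
    if isinstance(model, SelpccaModel):
        mats = [model.hatalpha, model.hatbeta]
        if view not in (0, 1):
            raise ValidationError("SELPCCA models have views 0 and 1")
        return mats[view], model.feature_names[view]
    if isinstance(model, SidaModel):
        if not 0 <= view < len(model.hatalpha):
            raise ValidationError(f"view index {view} out of range")
        return model.hatalpha[view], model.feature_names[view]
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def _view_scores(model, X: np.ndarray, view: int) -> np.ndarray:
    G, _ = _view_loadings(model, view)
    X = np.asarray(X, dtype=float)
    if isinstance(model, SidaModel):
        X = X - model.col_means[view]
    return X @ G


def importance_table(model, view: int = 0, component: int = 0, top_n: int = 20) -> pd.DataFrame:
    """Top ``top_n`` variables by absolute loading on one component."""
    G, names = _view_loadings(model, view)
    if not 0 <= component < G.shape[1]:
        raise ValidationError(f"component {component} out of range (K={G.shape[1]})")
    load = G[:, component]
    nz = np.flatnonzero(load != 0)
    if nz.size == 0:
        warnings.warn("all loadings are zero for this component", stacklevel=2)
        return pd.DataFrame(columns=["name", "loading", "abs_loading"])
    df = pd.DataFrame({
        "name": [names[i] for i in nz],
        "loading": load[nz],
        "abs_loading": np.abs(load[nz]),
    })
    df = df.sort_values(["abs_loading", "name"], ascending=[False, True],
                        kind="stable").head(top_n)
    return df.reset_index(drop=True)


def discriminant_table(model, views: list[np.ndarray], labels: np.ndarray,
                       sample_ids: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Per view: sample scores on the first one/two discriminant directions."""
    if labels is None:
        raise ValidationError("discriminant plots require class labels")
    out = {}
    n_views = len(model.hatalpha) if isinstance(model, SidaModel) else 2
    for d in range(min(len(views), n_views)):
        S = _view_scores(model, views[d], d)
        ids = sample_ids if sample_ids is not None else [str(i) for i in range(S.shape[0])]
        cols = {"sample_id": ids, "score_1": S[:, 0]}
        if S.shape[1] >= 2:
            cols["score_2"] = S[:, 1]
        cols["class"] = labels
        vname = (model.view_names[d] if hasattr(model, "view_names") else f"view{d + 1}")
        out[vname] = pd.DataFrame(cols)
    return out


def correlation_table(model, views: list[np.ndarray], labels: np.ndarray,
                      sample_ids: list[str] | None = None) -> dict[tuple[str, str], pd.DataFrame]:
    """Per view pair: first-component scores side by side, Pearson r in attrs."""
    out = {}
    n_views = 2 if isinstance(model, SelpccaModel) else len(model.hatalpha)
    n_views = min(n_views, len(views))
    for d in range(n_views):
        for j in range(d + 1, n_views):
            sd = _view_scores(model, views[d], d)[:, 0]
            sj = _view_scores(model, views[j], j)[:, 0]
            ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(sd))]
            df = pd.DataFrame({
                "sample_id": ids,
                "score_view_1": sd,
                "score_view_2": sj,
                "class": labels,
            })
            r = (float(np.corrcoef(sd, sj)[0, 1])
                 if sd.std() > 0 and sj.std() > 0 else 0.0)
            df.attrs["pearson_r"] = r
            names = (model.view_names if hasattr(model, "view_names")
                     else [f"view{i + 1}" for i in range(n_views)])
            out[(names[d], names[j])] = df
    return out


def relevance_network(model, X1: np.ndarray, X2: np.ndarray,
                      cutoff: float = 0.5) -> RelevanceGraph:
    """Signed bipartite correlation network between the two views' selected
    variables.  Edge weight = empirical Pearson correlation of the two
    variables' training columns; edges kept when ``|weight| >= cutoff``;
    isolated nodes are dropped."""
    if not 0 <= cutoff <= 1:
        raise ValidationError("cutoff must be in [0, 1]")
    G1, names1 = _view_loadings(model, 0)
    G2, names2 = _view_loadings(model, 1)
    sel1 = np.flatnonzero(np.any(G1 != 0, axis=1))
    sel2 = np.flatnonzero(np.any(G2 != 0, axis=1))
    X1 = np.asarray(X1, dtype=float)[:, sel1]
    X2 = np.asarray(X2, dtype=float)[:, sel2]
    edges = []
    if sel1.size and sel2.size:
        C = np.corrcoef(X1, X2, rowvar=False)[: sel1.size, sel1.size:]
        C = np.nan_to_num(C, nan=0.0)
        keep = np.argwhere(np.abs(C) >= cutoff)
        for i, j in keep:
            w = float(C[i, j])
            edges.append((names1[sel1[i]], names2[sel2[j]], w,
                          "solid" if w >= 0 else "dashed"))
    edges_df = pd.DataFrame(edges, columns=["node1", "node2", "weight", "sign"])
    used1 = set(edges_df["node1"]) if len(edges_df) else set()
    used2 = set(edges_df["node2"]) if len(edges_df) else set()
    nodes = [(1, names1[i], "circle") for i in sel1 if names1[i] in used1]
    nodes += [(2, names2[j], "rectangle") for j in sel2 if names2[j] in used2]
    nodes_df = pd.DataFrame(nodes, columns=["view", "name", "shape"])
    return RelevanceGraph(nodes=nodes_df, edges=edges_df, cutoff=cutoff)


def loadings_table(model, view: int = 0) -> pd.DataFrame:
    """(name, loading_comp1, loading_comp2) for variables with any nonzero
    loading; the second column is zero for single-component models."""
    G, names = _view_loadings(model, view)
    nz = np.flatnonzero(np.any(G != 0, axis=1))
    c2 = G[nz, 1] if G.shape[1] >= 2 else np.zeros(nz.size)
    return pd.DataFrame({
        "name": [names[i] for i in nz],
        "loading_comp1": G[nz, 0],
        "loading_comp2": c2,
    })


def _arrows(X: np.ndarray, s1: np.ndarray, s2: np.ndarray, names: list[str],
            top_n: int) -> pd.DataFrame:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    a1 = np.zeros(X.shape[1])
    a2 = np.zeros(X.shape[1])
    ok = sd > 0
    if s1.std() > 0:
        a1[ok] = [float(np.corrcoef(X[:, j], s1)[0, 1]) for j in np.flatnonzero(ok)]
    if s2.std() > 0:
        a2[ok] = [float(np.corrcoef(X[:, j], s2)[0, 1]) for j in np.flatnonzero(ok)]
    length = np.hypot(a1, a2)
    order = np.argsort(-length, kind="stable")[:top_n]
    return pd.DataFrame({
        "name": [names[j] for j in order],
        "a1": a1[order],
        "a2": a2[order],
    })


def _two_scores(model, X: np.ndarray, view: int) -> tuple[np.ndarray, np.ndarray]:
    S = _view_scores(model, np.asarray(X, dtype=float), view)
    s1 = S[:, 0]
    s2 = S[:, 1] if S.shape[1] >= 2 else np.zeros_like(s1)
    return s1, s2


def biplot_within(model, X: np.ndarray, labels: np.ndarray, view: int = 0,
                  sample_ids: list[str] | None = None,
                  top_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation biplot for one view: (samples table, arrows table).

    Arrow coordinates are the Pearson correlations of each variable's column
    with the first two score axes, so every arrow lies in the unit disk.
    """
    s1, s2 = _two_scores(model, X, view)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(s1))]
    samples = pd.DataFrame({
        "sample_id": ids, "score_1": s1, "score_2": s2, "class": labels,
    })
    _, names = _view_loadings(model, view)
    arrows = _arrows(X, s1, s2, names, top_n)
    return samples, arrows


def biplot_between(model, X1: np.ndarray, X2: np.ndarray, labels: np.ndarray,
                   sample_ids: list[str] | None = None,
                   top_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-view correlation biplot: both views' selected variables drawn
    against view 1's score axes (view-1 arrows tagged solid, view-2 dashed)."""
    s1, s2 = _two_scores(model, X1, 0)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(s1))]
    samples = pd.DataFrame({
        "sample_id": ids, "score_1": s1, "score_2": s2, "class": labels,
    })
    _, names1 = _view_loadings(model, 0)
    _, names2 = _view_loadings(model, 1)
    arr1 = _arrows(X1, s1, s2, names1, top_n)
    arr1["view"] = 1
    arr1["style"] = "solid"
    arr2 = _arrows(X2, s1, s2, names2, top_n)
    arr2["view"] = 2
    arr2["style"] = "dashed"
    return samples, pd.concat([arr1, arr2], ignore_index=True)


# ---------------------------------------------------------------------------
# rendering (thin wrappers; no logic beyond drawing the tables)
# ---------------------------------------------------------------------------

def _fig():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def render_volcano(table: pd.DataFrame, path: str) -> None:
    plt = _fig()
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = table["significant"].astype(bool)
    ax.scatter(table.loc[~sig, "effect"], table.loc[~sig, "neg_log10_adj_p"],
               s=8, c="grey", alpha=0.6)
    ax.scatter(table.loc[sig, "effect"], table.loc[sig, "neg_log10_adj_p"],
               s=8, c="crimson")
    ax.set_xlabel("effect")
    ax.set_ylabel("-log10 adjusted p")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_scatter(table: pd.DataFrame, xcol: str, ycol: str, path: str,
                   label_col: str | None = "class") -> None:
    plt = _fig()
    fig, ax = plt.subplots(figsize=(5, 4))
    if label_col and label_col in table.columns:
        for lab, grp in table.groupby(label_col):
            ax.scatter(grp[xcol], grp[ycol], s=10, label=str(lab))
        ax.legend(fontsize=7)
    else:
        ax.scatter(table[xcol], table[ycol], s=10)
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_importance(table: pd.DataFrame, path: str) -> None:
    plt = _fig()
    fig, ax = plt.subplots(figsize=(5, max(2, 0.25 * len(table))))
    t = table.iloc[::-1]
    ax.barh(t["name"], t["abs_loading"],
            color=np.where(t["loading"] >= 0, "steelblue", "indianred"))
    ax.set_xlabel("|loading|")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_discriminant(table: pd.DataFrame, path: str) -> None:
    plt = _fig()
    fig, ax = plt.subplots(figsize=(5, 4))
    if "score_2" in table.columns:
        for lab, grp in table.groupby("class"):
            ax.scatter(grp["score_1"], grp["score_2"], s=10, label=str(lab))
    else:
        for lab, grp in table.groupby("class"):
            ax.hist(grp["score_1"], bins=20, alpha=0.5, density=True, label=str(lab))
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_network(graph: RelevanceGraph, path: str) -> None:
    import networkx as nx

    plt = _fig()
    G = nx.Graph()
    for _, row in graph.nodes.iterrows():
        G.add_node(row["name"], view=row["view"], shape=row["shape"])
    for _, row in graph.edges.iterrows():
        G.add_edge(row["node1"], row["node2"], weight=row["weight"], sign=row["sign"])
    fig, ax = plt.subplots(figsize=(6, 6))
    if len(G):
        pos = nx.spring_layout(G, seed=0)
        v1 = [n for n, d in G.nodes(data=True) if d["view"] == 1]
        v2 = [n for n, d in G.nodes(data=True) if d["view"] == 2]
        nx.draw_networkx_nodes(G, pos, nodelist=v1, node_shape="o",
                               node_color="lightblue", node_size=120, ax=ax)
        nx.draw_networkx_nodes(G, pos, nodelist=v2, node_shape="s",
                               node_color="lightsalmon", node_size=120, ax=ax)
        solid = [(u, v) for u, v, d in G.edges(data=True) if d["sign"] == "solid"]
        dashed = [(u, v) for u, v, d in G.edges(data=True) if d["sign"] == "dashed"]
        nx.draw_networkx_edges(G, pos, edgelist=solid, style="solid", ax=ax)
        nx.draw_networkx_edges(G, pos, edgelist=dashed, style="dashed", ax=ax)
        nx.draw_networkx_labels(G, pos, font_size=6, ax=ax)
    ax.set_axis_off()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_biplot(samples: pd.DataFrame, arrows: pd.DataFrame, path: str) -> None:
    plt = _fig()
    fig, ax = plt.subplots(figsize=(5, 5))
    for lab, grp in samples.groupby("class"):
        ax.scatter(grp["score_1"], grp["score_2"], s=10, label=str(lab))
    scale = max(float(samples[["score_1", "score_2"]].abs().max().max()), 1.0)
    for _, row in arrows.iterrows():
        style = row.get("style", "solid")
        color = "black" if style == "solid" else "red"
        ax.annotate("", xy=(row["a1"] * scale, row["a2"] * scale), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color=color,
                                    linestyle=style))
        ax.text(row["a1"] * scale, row["a2"] * scale, row["name"], fontsize=6)
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=100)
    plt.close(fig)
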