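"""Sparse integrative discriminant analysis for two or more views.

Each view receives sparse discriminant directions that trade off within-view
class separation (a between-class scatter term) against cross-view association
(projected cross-covariances with the other views' current directions),
controlled by a balance weight.  Directions are estimated by an alternating
eigen-decomposition + soft-threshold scheme; the per-view thresholds are
picked by stratified cross-validation minimizing held-out nearest-centroid
misclassification.  A network-structured variant replaces the eigen step with
a generalized eigenproblem penalized by the normalized graph Laplacian of a
per-view variable-variable network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import linalg

from .core_data import MultiViewData
from .exceptions import NoSelectionError, ValidationError
from .serialize import register_model

__all__ = [
    "VariableNetwork",
    "SidaModel",
    "normalized_laplacian",
    "class_scatter",
    "fit_sida",
    "fit_sidanet",
    "classify_sida",
]


def normalized_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """L = I - D^(-1/2) A D^(-1/2); rows/columns of isolated nodes are zero.

    The input must be square, symmetric, entrywise nonnegative with a zero
    diagonal.  Eigenvalues of the result lie in [0, 2].
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValidationError("adjacency must be nonnegative")
    if np.any(np.abs(np.diag(A)) > 1e-12):
        raise ValidationError("adjacency must have a zero diagonal")
    deg = A.sum(axis=1)
    nz = deg > 0
    L = np.zeros_like(A)
    if np.any(nz):
        inv_sqrt = np.zeros_like(deg)
        inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
        core = -inv_sqrt[:, None] * A * inv_sqrt[None, :]
        core[np.diag_indices_from(core)] = 0.0
        L = core
        L[nz, nz] = 1.0
        L[~nz, :] = 0.0
        L[:, ~nz] = 0.0
    return L


@register_model
@dataclass
class VariableNetwork:
    """Variable-variable adjacency for one view plus its normalized Laplacian."""

    view_name: str
    adjacency: np.ndarray
    normalized_laplacian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.normalized_laplacian = normalized_laplacian(self.adjacency)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


@register_model
@dataclass
class SidaModel:
    """Fitted sparse integrative discriminant model."""

    hatalpha: list[np.ndarray]  # per-view p_d x q loadings
    opt_lambda: np.ndarray  # per penalized view
    balance: float
    view_names: list[str]
    feature_names: list[list[str]]
    class_labels: np.ndarray
    col_means: list[np.ndarray]  # training centering per view
    centroids: list[np.ndarray]  # per-view K x q class centroids (train scores)
    train_scores: list[np.ndarray]
    train_correlation: float
    train_error: float
    kappa: float = 0.0
    has_covariates: bool = False
    converged: bool = True
    cv_error: float | None = None

    @property
    def n_views(self) -> int:
        return len(self.hatalpha) - (1 if self.has_covariates else 0)


def class_scatter(Xc: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and total covariance of column-centered data.

    S_t = X'X/(n-1); S_b = sum_k (n_k/n) m_k m_k' with m_k the class-k mean
    of the centered data.  rank(S_b) <= K - 1.
    """
    Xc = np.asarray(Xc, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("class_scatter requires >= 2 classes")
    n = Xc.shape[0]
    St = Xc.T @ Xc / (n - 1)
    Sb = np.zeros((Xc.shape[1], Xc.shape[1]))
    for cls in classes:
        mask = labels == cls
        m = Xc[mask].mean(axis=0)
        Sb += (mask.sum() / n) * np.outer(m, m)
    return Sb, St


def _top_eigh(A: np.ndarray, q: int, B: np.ndarray | None = None):
    """Top-q (generalized) eigenpairs, descending, sign-fixed, unit-norm."""
    if B is None:
        vals, vecs = linalg.eigh(A)
    else:
        vals, vecs = linalg.eigh(A, B)
    order = np.argsort(vals)[::-1][:q]
    V = vecs[:, order]
    for l in range(V.shape[1]):
        col = V[:, l]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            col = -col
        nrm = np.linalg.norm(col)
        V[:, l] = col / nrm if nrm > 0 else col
    return np.maximum(vals[order], 0.0), V


def _soft_unit(c: np.ndarray, tau: float) -> np.ndarray:
    u = np.sign(c) * np.maximum(0.0, np.abs(c) - tau)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise NoSelectionError(f"empty support at lambda={tau}")
    return u / nrm


def _fit_at_lambda(
    Xc: list[np.ndarray],
    labels: np.ndarray,
    lambdas: list[float],
    q: int,
    balance: float,
    laplacians: list[np.ndarray | None],
    kappa: float,
    tol: float = 1e-4,
    maxit: int = 20,
):
    """Alternating estimation of per-view sparse discriminant directions at
    fixed thresholds.  Returns (loadings list, converged flag)."""
    D = len(Xc)
    n = Xc[0].shape[0]
    Sb = [class_scatter(X, labels)[0] for X in Xc]
    M = {}
    for d in range(D):
        for j in range(D):
            if d != j:
                M[d, j] = Xc[d].T @ Xc[j] / (n - 1)

    gammas = []
    for d in range(D):
        _, V = _top_eigh(Sb[d], q)
        gammas.append(V)

    def build_A(d):
        A = balance * Sb[d]
        if D > 1:
            assoc = np.zeros_like(A)
            for j in range(D):
                if j == d:
                    continue
                P = M[d, j] @ gammas[j]
                assoc += P @ P.T
            A = A + (1.0 - balance) * assoc / (D - 1)
        return A

    prev_obj = None
    converged = False
    for _ in range(maxit):
        for d in range(D):
            A = build_A(d)
            B = None
            if laplacians[d] is not None and kappa != 0.0:
                B = np.eye(A.shape[0]) + kappa * laplacians[d]
            vals, V = _top_eigh(A, q, B)
            if lambdas[d] == 0.0:
                gammas[d] = V
            else:
                cols = []
                for l in range(q):
                    cvec = A @ V[:, l]
                    try:
                        cols.append(_soft_unit(cvec, lambdas[d]))
                    except NoSelectionError:
                        if l == 0:
                            raise
                        # trailing components may carry no signal at this
                        # threshold; keep them empty rather than failing
                        cols.append(np.zeros_like(cvec))
                gammas[d] = np.column_stack(cols)
        obj = sum(float(np.trace(gammas[d].T @ build_A(d) @ gammas[d])) for d in range(D))
        if prev_obj is not None and abs(obj - prev_obj) < tol:
            converged = True
            break
        prev_obj = obj
    return gammas, converged


def _scores_and_centroids(Xc, gammas, labels, classes):
    scores = [X @ G for X, G in zip(Xc, gammas)]
    centroids = []
    for S in scores:
        cent = np.vstack([S[labels == cls].mean(axis=0) for cls in classes])
        centroids.append(cent)
    return scores, centroids


def _nearest_centroid(scores, centroids, classes):
    n = scores[0].shape[0]
    dist = np.zeros((n, len(classes)))
    for S, C in zip(scores, centroids):
        diff = S[:, None, :] - C[None, :, :]
        dist += np.sum(diff**2, axis=2)
    return classes[np.argmin(dist, axis=1)]


def _stratified_folds(labels, folds, rng):
    fold_of = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        fold_of[members] = np.arange(len(members)) % folds
    return fold_of


def _auto_lambda_grid(Xc, labels, q, balance, laplacians, kappa, size=8):
    """Bracket each view's threshold from the first-iteration c-vector."""
    grids = []
    gammas, _ = _fit_at_lambda(Xc, labels, [0.0] * len(Xc), q, balance,
                               laplacians, kappa, maxit=1)
    D = len(Xc)
    n = Xc[0].shape[0]
    Sb = [class_scatter(X, labels)[0] for X in Xc]
    for d in range(D):
        A = balance * Sb[d]
        if D > 1:
            assoc = np.zeros_like(A)
            for j in range(D):
                if j == d:
                    continue
                Mdj = Xc[d].T @ Xc[j] / (n - 1)
                P = Mdj @ gammas[j]
                assoc += P @ P.T
            A = A + (1.0 - balance) * assoc / (D - 1)
        cmax = float(np.max(np.abs(A @ gammas[d][:, 0])))
        grids.append(np.geomspace(0.05 * cmax, 0.95 * cmax, size) if cmax > 0
                     else np.zeros(size))
    return grids


def fit_sida(
    train: MultiViewData,
    lambda_grid: list[np.ndarray] | None = None,
    folds: int = 5,
    balance: float = 0.5,
    with_covariates: bool = False,
    seed: int | None = None,
    n_components: int | None = None,
    _laplacians: list[np.ndarray] | None = None,
    _kappa: float = 0.0,
) -> SidaModel:
    """Cross-validated sparse integrative discriminant analysis.

    Per-view thresholds are selected over a (possibly automatic) grid by
    stratified ``folds``-fold CV minimizing held-out nearest-centroid error;
    among grids within one standard error of the best, the sparsest (largest
    threshold sum) wins.  Covariates, when requested, enter as an extra
    unpenalized view.
    """
    if train.n_views < 2:
        raise ValidationError("SIDA requires at least two views")
    if train.outcome is None or train.outcome.kind not in ("binary", "multiclass"):
        raise ValidationError("SIDA requires a class-valued outcome")
    if not 0 < balance <= 1:
        raise ValidationError("balance weight must be in (0, 1]")
    labels = np.asarray(train.outcome.values)
    classes = np.unique(labels)
    K = len(classes)
    q = n_components if n_components is not None else max(K - 1, 1)
    n = train.n_samples
    if n < 2 * folds:
        raise ValidationError(f"need n >= 2*folds (n={n}, folds={folds})")

    views = list(train.views)
    penalized = [True] * len(views)
    if with_covariates:
        if train.covariates is None:
            raise ValidationError("with_covariates=True but no covariates present")
        views.append(np.asarray(train.covariates, dtype=float))
        penalized.append(False)
    D = len(views)
    laplacians: list[np.ndarray | None]
    if _laplacians is not None:
        laplacians = list(_laplacians) + [None] * (D - len(_laplacians))
    else:
        laplacians = [None] * D

    col_means = [X.mean(axis=0) for X in views]
    Xc = [X - m for X, m in zip(views, col_means)]

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(labels, folds, rng)

    pen_idx = [d for d in range(D) if penalized[d]]
    if lambda_grid is None:
        grids = _auto_lambda_grid(Xc, labels, q, balance, laplacians, _kappa)
        grids = [grids[d] for d in pen_idx]
    else:
        grids = [np.asarray(g, dtype=float) for g in lambda_grid]
        if len(grids) != len(pen_idx):
            raise ValidationError("one lambda grid per penalized view required")

    combos = list(product(*[range(len(g)) for g in grids]))
    cv_err = np.full((len(combos), folds), np.nan)
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        Xtr = [X[tr] for X in views]
        mtr = [X.mean(axis=0) for X in Xtr]
        Xtr_c = [X - m for X, m in zip(Xtr, mtr)]
        Xte_c = [X[te] - m for X, m in zip(views, mtr)]
        ytr, yte = labels[tr], labels[te]
        if len(np.unique(ytr)) < K:
            continue  # fold lost a class entirely; stratification prevents this
        for i, combo in enumerate(combos):
            lams = [0.0] * D
            for gi, d in enumerate(pen_idx):
                lams[d] = float(grids[gi][combo[gi]])
            try:
                gammas, _ = _fit_at_lambda(Xtr_c, ytr, lams, q, balance,
                                           laplacians, _kappa)
            except NoSelectionError:
                continue
            _, cents = _scores_and_centroids(Xtr_c, gammas, ytr, classes)
            pred = _nearest_centroid([X @ G for X, G in zip(Xte_c, gammas)],
                                     cents, classes)
            cv_err[i, f] = float(np.mean(pred != yte))

    valid = ~np.any(np.isnan(cv_err), axis=1)
    if not np.any(valid):
        raise NoSelectionError("every lambda combination produced an empty support")
    mean_err = np.full(len(combos), np.inf)
    mean_err[valid] = cv_err[valid].mean(axis=1)
    best = int(np.argmin(mean_err))
    se = float(np.std(cv_err[best], ddof=1) / np.sqrt(folds))
    threshold = mean_err[best] + se
    candidates = [i for i in range(len(combos)) if mean_err[i] <= threshold]
    chosen = max(
        candidates,
        key=lambda i: (sum(grids[gi][combos[i][gi]] for gi in range(len(grids))),
                       -mean_err[i]),
    )
    lams = [0.0] * D
    for gi, d in enumerate(pen_idx):
        lams[d] = float(grids[gi][combos[chosen][gi]])

    gammas, conv = _fit_at_lambda(Xc, labels, lams, q, balance, laplacians, _kappa)
    if not conv:
        warnings.warn("SIDA alternating refit hit the iteration cap", stacklevel=2)
    scores, centroids = _scores_and_centroids(Xc, gammas, labels, classes)
    pred_train = _nearest_centroid(scores, centroids, classes)
    train_error = float(np.mean(pred_train != labels))

    first_cols = [S[:, 0] for S in scores[: train.n_views]]
    corrs = []
    for a in range(len(first_cols)):
        for b in range(a + 1, len(first_cols)):
            sa, sb = first_cols[a], first_cols[b]
            if sa.std() > 0 and sb.std() > 0:
                corrs.append(abs(np.corrcoef(sa, sb)[0, 1]))
    train_correlation = float(np.mean(corrs)) if corrs else 0.0

    feature_names = [list(f) for f in train.feature_names]
    view_names = list(train.view_names)
    if with_covariates:
        feature_names.append(list(train.covariate_names))
        view_names.append("covariates")

    return SidaModel(
        hatalpha=gammas,
        opt_lambda=np.asarray([lams[d] for d in pen_idx]),
        balance=balance,
        view_names=view_names,
        feature_names=feature_names,
        class_labels=classes,
        col_means=col_means,
        centroids=centroids,
        train_scores=scores,
        train_correlation=train_correlation,
        train_error=train_error,
        kappa=_kappa,
        has_covariates=with_covariates,
        converged=conv,
        cv_error=float(mean_err[chosen]),
    )


def fit_sidanet(
    train: MultiViewData,
    networks: list[VariableNetwork | None],
    kappa: float = 1.0,
    lambda_grid: list[np.ndarray] | None = None,
    folds: int = 5,
    balance: float = 0.5,
    with_covariates: bool = False,
    seed: int | None = None,
    n_components: int | None = None,
) -> SidaModel:
    """Network-structured SIDA: the nonsparse step solves the generalized
    eigenproblem A g = eta (I + kappa L) g with L the per-view normalized
    Laplacian.  With kappa = 0 or empty networks this reduces exactly to
    :func:`fit_sida`."""
    if len(networks) != train.n_views:
        raise ValidationError("one network (or None) per view required")
    laps = []
    for net, X, vname in zip(networks, train.views, train.view_names):
        if net is None:
            laps.append(None)
            continue
        if net.adjacency.shape[0] != X.shape[1]:
            raise ValidationError(
                f"network for {vname!r} has {net.adjacency.shape[0]} nodes, "
                f"view has {X.shape[1]} features"
            )
        L = net.normalized_laplacian
        laps.append(None if not np.any(L) else L)
    if kappa == 0.0 or all(L is None for L in laps):
        return fit_sida(train, lambda_grid=lambda_grid, folds=folds, balance=balance,
                        with_covariates=with_covariates, seed=seed,
                        n_components=n_components)
    return fit_sida(train, lambda_grid=lambda_grid, folds=folds, balance=balance,
                    with_covariates=with_covariates, seed=seed,
                    n_components=n_components, _laplacians=laps, _kappa=kappa)


def classify_sida(
    model: SidaModel,
    new_views: list[np.ndarray],
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Nearest-centroid classification of new samples.

    Each view is centered with the model's training means, projected onto its
    loadings, and samples are assigned to the class minimizing the summed
    squared distance to the per-view centroids (ties go to the lowest label).
    Returns (labels, per-view score matrices).
    """
    expected = model.n_views
    if len(new_views) != expected:
        raise ValidationError(f"model expects {expected} views, got {len(new_views)}")
    mats = [np.asarray(X, dtype=float) for X in new_views]
    if model.has_covariates:
        if covariates is None:
            raise ValidationError("model was fitted with covariates; none supplied")
        mats.append(np.asarray(covariates, dtype=float))
    for X, G, vname in zip(mats, model.hatalpha, model.view_names):
        if X.shape[1] != G.shape[0]:
            raise ValidationError(
                f"view {vname!r}: expected {G.shape[0]} features, got {X.shape[1]}"
            )
    scores = [(X - m) @ G for X, m, G in zip(mats, model.col_means, model.hatalpha)]
    labels = _nearest_centroid(scores, model.centroids, model.class_labels)
    return labels, scores
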