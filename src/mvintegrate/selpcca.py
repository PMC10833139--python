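"""Sparse canonical correlation analysis (two views).

The estimator couples a nonsparse CCA initializer (SVD of the cross-covariance
with within-view covariances treated as identity) with an l1-minimal
sparsification step under an infinity-norm residual constraint.  With the
diagonal constraint used here that subproblem has the closed-form
coordinate-wise soft-thresholding solution, so each canonical direction is
obtained by alternating soft-threshold-and-normalize updates between the two
views.  Successive components are found after Hotelling deflation of the
cross-covariance with the nonsparse singular triplets.  The per-view
thresholds are chosen by k-fold cross-validation maximizing mean held-out
absolute correlation of the canonical scores, with ties (within one standard
error of the best) broken toward the sparser model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import MultiViewData
from .exceptions import NoSelectionError, ValidationError
from .serialize import register_model

__all__ = [
    "SelpccaModel",
    "initial_cca",
    "selp_sparsify",
    "cv_selpcca",
    "transform_scores",
]


@register_model
@dataclass
class SelpccaModel:
    """Fitted sparse CCA model for a pair of views."""

    hatalpha: np.ndarray  # p1 x K canonical loadings, view 1
    hatbeta: np.ndarray  # p2 x K canonical loadings, view 2
    opt_tau: np.ndarray  # 2 x K selected thresholds (row 0: view 1)
    maxcorr: np.ndarray  # K absolute train canonical correlations
    train_scores_u: np.ndarray  # n x K, X1 @ hatalpha on raw training data
    train_scores_v: np.ndarray
    feature_names: list[list[str]]
    view_names: list[str]
    ncancorr: int
    nonzero: np.ndarray  # 2 x K support sizes
    converged: list[bool] = field(default_factory=list)
    cv_mean_corr: np.ndarray | None = None  # K, mean held-out |corr| at opt tau

    def __post_init__(self) -> None:
        for mat in (self.hatalpha, self.hatbeta):
            norms = np.linalg.norm(mat, axis=0)
            nz = norms > 0
            if not np.allclose(norms[nz], 1.0, atol=1e-8):
                raise ValidationError("nonzero loading columns must be unit-norm")
        if np.any(self.maxcorr < -1e-12) or np.any(self.maxcorr > 1 + 1e-12):
            raise ValidationError("maxcorr must lie in [0, 1]")


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def _fix_sign(v: np.ndarray) -> np.ndarray:
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def initial_cca(X1: np.ndarray, X2: np.ndarray, K: int = 1):
    """Nonsparse initializer: top-K singular triplets of S12 = X1'X2/(n-1).

    Columns of X1, X2 must already be centered.  Within-view covariances are
    treated as identity.  Returns (atilde p1 x K, btilde p2 x K, dvals K).
    Sign convention: the largest-magnitude entry of each atilde column is
    positive.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape[0] != X2.shape[0]:
        raise ValidationError("views must share the sample dimension")
    n = X1.shape[0]
    S12 = X1.T @ X2 / (n - 1)
    U, s, Vt = np.linalg.svd(S12, full_matrices=False)
    rank = int(np.sum(s > max(S12.shape) * np.finfo(float).eps * (s[0] if s.size else 0)))
    if K > rank:
        raise ValidationError(f"K={K} exceeds rank {rank} of the cross-covariance")
    A = np.empty((X1.shape[1], K))
    B = np.empty((X2.shape[1], K))
    for k in range(K):
        a = U[:, k]
        flip = -1.0 if a[int(np.argmax(np.abs(a)))] < 0 else 1.0
        A[:, k] = flip * a
        B[:, k] = flip * Vt[k]
    return A, B, s[:K].copy()


def selp_sparsify(
    c: np.ndarray,
    rho: float,
    tau: float,
    unit_norm: bool = True,
) -> np.ndarray:
    """Minimize ||u||_1 subject to ||c - rho*u||_inf <= tau.

    The constraint is separable, so the solution is coordinate-wise
    soft-thresholding: u_j = sign(c_j) * max(0, |c_j| - tau) / rho.
    The result is rescaled to unit Euclidean norm unless ``unit_norm=False``.
    Raises :class:`NoSelectionError` if every coordinate is thresholded away.
    """
    if rho <= 0:
        raise ValidationError("rho must be positive")
    if tau < 0:
        raise ValidationError("tau must be nonnegative")
    c = np.asarray(c, dtype=float)
    u = np.sign(c) * np.maximum(0.0, np.abs(c) - tau) / rho
    if not np.any(u):
        raise NoSelectionError(f"no variables selected at tau={tau}")
    return _unit(u) if unit_norm else u


def _alternating_fit(S, a0, b0, tau1, tau2, tol=1e-6, maxit=50):
    """Alternating SELP updates of one canonical pair on a fixed (deflated)
    cross-covariance.  Returns (a, b, converged)."""
    a, b = a0.copy(), b0.copy()
    for _ in range(maxit):
        c1 = S @ b
        a_new = np.sign(c1) * np.maximum(0.0, np.abs(c1) - tau1)
        if not np.any(a_new):
            raise NoSelectionError(f"view-1 update empty at tau={tau1}")
        a_new = _unit(a_new)
        c2 = S.T @ a_new
        b_new = np.sign(c2) * np.maximum(0.0, np.abs(c2) - tau2)
        if not np.any(b_new):
            raise NoSelectionError(f"view-2 update empty at tau={tau2}")
        b_new = _unit(b_new)
        delta = max(np.max(np.abs(a_new - a)), np.max(np.abs(b_new - b)))
        a, b = a_new, b_new
        if delta < tol:
            return a, b, True
    return a, b, False


def _abs_corr(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(abs(np.corrcoef(u, v)[0, 1]))


def _auto_grid(cmax: float, size: int = 10) -> np.ndarray:
    if cmax <= 0:
        return np.zeros(size)
    return np.geomspace(0.05 * cmax, 0.95 * cmax, size)


def cv_selpcca(
    train: MultiViewData,
    ncancorr: int = 1,
    tau_grid: tuple[np.ndarray, np.ndarray] | None = None,
    folds: int = 5,
    seed: int | None = None,
) -> SelpccaModel:
    """Cross-validated sparse CCA on a two-view training set.

    For each component the per-view threshold pair is chosen over the grid by
    ``folds``-fold CV maximizing mean held-out |corr(X1 a, X2 b)|; among pairs
    within one standard error of the best, the sparsest (largest tau sum)
    wins.  The model is then refit at the selected pair on the full training
    data, the cross-covariance is deflated with the nonsparse triplet, and the
    next component is estimated.
    """
    if train.n_views != 2:
        raise ValidationError("SELPCCA requires exactly two views")
    X1, X2 = train.views
    n = X1.shape[0]
    if n < 2 * folds:
        raise ValidationError(f"need n >= 2*folds (n={n}, folds={folds})")
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    fold_of = fold_of[rng.permutation(n)]
    if min(np.bincount(fold_of, minlength=folds)) < 2:
        raise ValidationError("a CV fold has fewer than 2 samples")

    X1c = X1 - X1.mean(axis=0)
    X2c = X2 - X2.mean(axis=0)
    A_full, B_full, d_full = initial_cca(X1c, X2c, ncancorr)
    S_full = X1c.T @ X2c / (n - 1)

    # per-fold cross-covariances and their SVDs, shared across the grid
    fold_cache = []
    for f in range(folds):
        tr = fold_of != f
        F1 = X1[tr] - X1[tr].mean(axis=0)
        F2 = X2[tr] - X2[tr].mean(axis=0)
        Sf = F1.T @ F2 / (tr.sum() - 1)
        Uf, sf, Vtf = np.linalg.svd(Sf, full_matrices=False)
        fold_cache.append((Sf, Uf, sf, Vtf, ~tr))

    hatalpha = np.zeros((X1.shape[1], ncancorr))
    hatbeta = np.zeros((X2.shape[1], ncancorr))
    opt_tau = np.zeros((2, ncancorr))
    maxcorr = np.zeros(ncancorr)
    cv_best = np.zeros(ncancorr)
    converged_flags = []

    S_defl = S_full.copy()
    fold_defl = [fc[0].copy() for fc in fold_cache]

    for k in range(ncancorr):
        a0, b0, d0 = A_full[:, k], B_full[:, k], d_full[k]
        if tau_grid is None:
            g1 = _auto_grid(np.max(np.abs(S_defl @ b0)))
            g2 = _auto_grid(np.max(np.abs(S_defl.T @ a0)))
        else:
            g1 = np.asarray(tau_grid[0], dtype=float)
            g2 = np.asarray(tau_grid[1], dtype=float)

        pairs = [(t1, t2) for t1 in g1 for t2 in g2]
        scores = np.full((len(pairs), folds), np.nan)
        for f, (Sf, Uf, sf, Vtf, te) in enumerate(fold_cache):
            Sdf = fold_defl[f]
            if k >= sf.size:
                continue
            af = Uf[:, k]
            flip = -1.0 if af[int(np.argmax(np.abs(af)))] < 0 else 1.0
            af = flip * af
            bf = flip * Vtf[k]
            for i, (t1, t2) in enumerate(pairs):
                try:
                    a, b, _ = _alternating_fit(Sdf, af, bf, t1, t2)
                except NoSelectionError:
                    continue
                scores[i, f] = _abs_corr(X1[te] @ a, X2[te] @ b)
        valid = ~np.any(np.isnan(scores), axis=1)
        mean_scores = np.where(valid, scores.mean(axis=1), -np.inf)
        if not np.any(valid):
            raise NoSelectionError(
                f"every tau pair produced an empty support for component {k + 1}"
            )
        best = int(np.argmax(mean_scores))
        se = float(np.std(scores[best], ddof=1) / np.sqrt(folds))
        threshold = mean_scores[best] - se
        candidates = [i for i in range(len(pairs)) if mean_scores[i] >= threshold]
        # ties (within one SE) -> sparser: maximize tau1 + tau2
        chosen = max(candidates, key=lambda i: (pairs[i][0] + pairs[i][1], mean_scores[i]))
        t1, t2 = pairs[chosen]

        a, b, conv = _alternating_fit(S_defl, a0, b0, t1, t2)
        if not conv:
            warnings.warn(f"component {k + 1}: alternating refit hit iteration cap",
                          stacklevel=2)
        converged_flags.append(conv)
        hatalpha[:, k] = a
        hatbeta[:, k] = b
        opt_tau[:, k] = (t1, t2)
        maxcorr[k] = _abs_corr(X1c @ a, X2c @ b)
        cv_best[k] = mean_scores[chosen]

        # Hotelling deflation with the *nonsparse* triplet
        S_defl = S_defl - d0 * np.outer(a0, b0)
        for f, (Sf, Uf, sf, Vtf, te) in enumerate(fold_cache):
            if k < sf.size:
                fold_defl[f] = fold_defl[f] - sf[k] * np.outer(Uf[:, k], Vtf[k])

    model = SelpccaModel(
        hatalpha=hatalpha,
        hatbeta=hatbeta,
        opt_tau=opt_tau,
        maxcorr=maxcorr,
        train_scores_u=X1 @ hatalpha,
        train_scores_v=X2 @ hatbeta,
        feature_names=[list(f) for f in train.feature_names],
        view_names=list(train.view_names),
        ncancorr=ncancorr,
        nonzero=np.vstack([(hatalpha != 0).sum(axis=0), (hatbeta != 0).sum(axis=0)]),
        converged=converged_flags,
        cv_mean_corr=cv_best,
    )
    return model


def transform_scores(
    model: SelpccaModel,
    X1new: np.ndarray,
    X2new: np.ndarray,
    feature_names: tuple[list[str], list[str]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project new (already preprocessed) matrices onto the canonical loadings."""
    X1new = np.asarray(X1new, dtype=float)
    X2new = np.asarray(X2new, dtype=float)
    if feature_names is not None:
        for new, ref, vname in zip(feature_names, model.feature_names, model.view_names):
            if list(new) != list(ref):
                bad = sorted(set(ref).symmetric_difference(new))
                raise ValidationError(f"feature mismatch in {vname}: {bad}")
    if X1new.shape[1] != model.hatalpha.shape[0] or X2new.shape[1] != model.hatbeta.shape[0]:
        raise ValidationError("new data column counts do not match the model")
    return X1new @ model.hatalpha, X2new @ model.hatbeta
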