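"""Per-view preprocessing and supervised/unsupervised feature filtering.

Transforms and filter statistics are always estimated on training data; the
resulting :class:`FilterResult` carries everything needed to map a test view
into the same space (same kept features, same training means/variances).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import MultiViewData, Outcome
from .exceptions import ValidationError

SUPERVISED_METHODS = ("linear", "logistic", "ttest", "kw")
UNSUPERVISED_METHODS = ("variance", "iqr")
ADJUST_METHODS = ("BH", "bonferroni", "none")


@dataclass
class TransformRecord:
    """Training-data transform parameters, re-applied verbatim to test data."""

    log2: bool = False
    center: bool = False
    scale: bool = False
    feature_names: list[str] | None = None
    means: np.ndarray | None = None
    stds: np.ndarray | None = None

    def apply(self, X: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.log2:
            if np.any(X <= -1):
                raise ValidationError("log2(x+1) undefined for values <= -1")
            X = np.log2(X + 1.0)
        if not (self.center or self.scale):
            return X
        means, stds = self.means, self.stds
        if feature_names is not None and self.feature_names is not None:
            pos = {f: i for i, f in enumerate(self.feature_names)}
            missing = [f for f in feature_names if f not in pos]
            if missing:
                raise ValidationError(f"features without stored transform params: {missing}")
            sel = [pos[f] for f in feature_names]
            means = means[sel] if means is not None else None
            stds = stds[sel] if stds is not None else None
        if self.center:
            X = X - means
        if self.scale:
            X = X / stds
        return X


def preprocess(
    X: np.ndarray,
    log2: bool = False,
    center: bool = False,
    scale: bool = False,
    normalize: bool = False,
    train_params: TransformRecord | None = None,
    feature_names: list[str] | None = None,
    on_zero_variance: str = "error",
) -> tuple[np.ndarray, TransformRecord]:
    """Apply log2(x+1)/centering/scaling to a view.

    ``normalize`` is shorthand for ``center`` + ``scale``.  When
    ``train_params`` is supplied the stored training means/variances are
    applied without re-estimation (the test-set path).
    """
    if train_params is not None:
        return train_params.apply(X, feature_names), train_params
    if normalize:
        center = scale = True
    X = np.asarray(X, dtype=float)
    rec = TransformRecord(log2=log2, center=center, scale=scale,
                          feature_names=list(feature_names) if feature_names else None)
    if log2:
        if np.any(X <= -1):
            raise ValidationError("log2(x+1) undefined for values <= -1")
        X = np.log2(X + 1.0)
    if center or scale:
        rec.means = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        if scale and np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            if on_zero_variance == "error":
                raise ValidationError(f"zero-variance columns under scaling: {bad.tolist()}")
            warnings.warn(f"scaling left zero-variance columns untouched: {bad.tolist()}",
                          stacklevel=2)
            sd = np.where(sd == 0, 1.0, sd)
        rec.stds = sd
        if center:
            X = X - rec.means
        if scale:
            X = X / rec.stds
    return X, rec


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg step-up, Bonferroni or none.

    NaN entries (e.g. non-converged per-feature fits) are ignored for the
    effective number of tests and propagate as NaN.
    """
    if method not in ADJUST_METHODS:
        raise ValidationError(f"unknown adjustment method {method!r}")
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    out = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    if method == "bonferroni":
        out[valid] = np.minimum(1.0, m * pv)
        return out
    order = np.argsort(pv, kind="stable")
    q = np.minimum(1.0, m * pv[order] / np.arange(1, m + 1))
    q = np.minimum.accumulate(q[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = q
    out[valid] = adj
    return out


@dataclass
class FilterResult:
    """Per-feature statistics and the retained-feature mask for one view."""

    view_name: str
    method: str
    table: pd.DataFrame  # columns: name, statistic, effect, p_value, p_adjusted, keep
    alpha: float | None = None
    keep_fraction: float | None = None
    transform: TransformRecord | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def kept_features(self) -> list[str]:
        return self.table.loc[self.table["keep"], "name"].tolist()


def _linear_tests(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # slope t-test of y ~ x, one feature at a time, vectorized
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (xc * yc[:, None]).sum(axis=0) / sxx
        resid = yc[:, None] - xc * beta
        s2 = (resid**2).sum(axis=0) / (n - 2)
        se = np.sqrt(s2 / sxx)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return t, beta, p


def _logistic_tests(X, y01, notes):
    import statsmodels.api as sm

    stat = np.full(X.shape[1], np.nan)
    eff = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        design = sm.add_constant(X[:, j])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y01, design).fit(disp=0, maxiter=100, method="newton")
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or not np.all(np.isfinite(res.bse)):
                raise RuntimeError("did not converge")
            eff[j] = res.params[1]
            stat[j] = res.params[1] / res.bse[1]
            p[j] = 2 * stats.norm.sf(abs(stat[j]))
        except Exception:
            notes.append(f"logistic fit failed for feature index {j} (separation?)")
    if any("logistic fit failed" in s for s in notes):
        warnings.warn("some logistic per-feature fits did not converge; "
                      "those features were excluded from selection", stacklevel=3)
    return stat, eff, p


def _two_group_tests(X, y, method):
    groups = np.unique(y)
    if method == "ttest" and len(groups) != 2:
        raise ValidationError("t-test requires a binary outcome")
    if len(groups) < 2:
        raise ValidationError("grouped tests require >= 2 groups")
    masks = [y == g for g in groups]
    if method == "ttest":
        if min(m.sum() for m in masks) < 3:
            raise ValidationError("t-test requires >= 3 samples per group")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(X[masks[1]], X[masks[0]], equal_var=False)
        stat, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    else:  # kw
        stat = np.empty(X.shape[1])
        p = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            samples = [X[m, j] for m in masks]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    h, pj = stats.kruskal(*samples)
            except ValueError:  # all values identical
                h, pj = np.nan, np.nan
            stat[j], p[j] = h, pj
    # constant features carry no signal: statistic 0, p 1
    dead = ~np.isfinite(stat)
    stat[dead] = 0.0
    p[dead] = 1.0
    if len(groups) == 2:
        eff = X[masks[1]].mean(axis=0) - X[masks[0]].mean(axis=0)
    else:
        eff = np.full(X.shape[1], np.nan)
    return stat, eff, p


def supervised_filter(
    X: np.ndarray,
    feature_names: list[str],
    outcome: Outcome,
    method: str = "linear",
    padjust: bool = True,
    adjmethod: str = "BH",
    alpha: float = 0.05,
    view_name: str = "view",
    transform: TransformRecord | None = None,
) -> FilterResult:
    """Keep features associated with the outcome by a per-feature test.

    Tests: ``linear`` slope test (continuous outcome), ``logistic`` Wald test
    (binary), Welch ``ttest`` (binary), ``kw`` Kruskal-Wallis (>= 2 groups).
    The effect column is the group-mean difference on the supplied (typically
    log2) scale for ttest/kw, and the model coefficient for linear/logistic.
    """
    if method not in SUPERVISED_METHODS:
        raise ValidationError(f"unknown supervised method {method!r}")
    X = np.asarray(X, dtype=float)
    notes: list[str] = []
    if method == "linear":
        if outcome.kind not in ("continuous", "count"):
            raise ValidationError("linear filtering requires a continuous outcome")
        y = np.asarray(outcome.values, dtype=float)
        stat, eff, p = _linear_tests(X, y)
        dead = ~np.isfinite(stat)
        stat[dead], p[dead] = 0.0, 1.0
    elif method == "logistic":
        if outcome.kind != "binary":
            raise ValidationError("logistic filtering requires a binary outcome")
        classes = outcome.classes
        y01 = (np.asarray(outcome.values) == classes[1]).astype(float)
        stat, eff, p = _logistic_tests(X, y01, notes)
    else:
        if outcome.kind not in ("binary", "multiclass"):
            raise ValidationError(f"{method} filtering requires a class-valued outcome")
        stat, eff, p = _two_group_tests(X, np.asarray(outcome.values), method)

    p_adj = adjust_pvalues(p, adjmethod if padjust else "none")
    crit = p_adj if padjust else p
    keep = np.where(np.isnan(crit), False, crit <= alpha)
    table = pd.DataFrame({
        "name": feature_names,
        "statistic": stat,
        "effect": eff,
        "p_value": p,
        "p_adjusted": p_adj if padjust else np.full(len(p), np.nan),
        "keep": keep,
    })
    return FilterResult(view_name=view_name, method=method, table=table,
                        alpha=alpha, transform=transform, notes=notes)


def unsupervised_filter(
    X: np.ndarray,
    feature_names: list[str],
    method: str = "variance",
    keep_fraction: float = 0.5,
    view_name: str = "view",
    transform: TransformRecord | None = None,
) -> FilterResult:
    """Keep the top ``ceil(keep_fraction * p)`` features by variance or IQR.

    Variance is the unbiased sample variance; IQR uses linear-interpolation
    (type-7) quartiles.  Ties are broken by original column order.
    """
    if method not in UNSUPERVISED_METHODS:
        raise ValidationError(f"unknown unsupervised method {method!r}")
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if method == "variance":
        score = X.var(axis=0, ddof=1)
    else:
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        score = q75 - q25
    if np.all(score == score[0]) and p > 1:
        warnings.warn("all features tie on the filtering statistic; "
                      "keeping the first columns", stacklevel=2)
    n_keep = math.ceil(keep_fraction * p)
    order = np.argsort(-score, kind="stable")
    keep = np.zeros(p, dtype=bool)
    keep[order[:n_keep]] = True
    table = pd.DataFrame({
        "name": feature_names,
        "statistic": score,
        "effect": np.full(p, np.nan),
        "p_value": np.full(p, np.nan),
        "p_adjusted": np.full(p, np.nan),
        "keep": keep,
    })
    return FilterResult(view_name=view_name, method=method, table=table,
                        keep_fraction=keep_fraction, transform=transform)


def apply_filter(
    X: np.ndarray,
    feature_names: list[str],
    result: FilterResult,
) -> tuple[np.ndarray, list[str]]:
    """Restrict a test view to the training kept features, in training order,
    and apply the stored training transform.  Extra test features are dropped
    silently; a missing kept feature is an error naming it."""
    kept = result.kept_features
    pos = {f: i for i, f in enumerate(feature_names)}
    missing = [f for f in kept if f not in pos]
    if missing:
        raise ValidationError(f"test view is missing kept features: {missing}")
    X = np.asarray(X, dtype=float)[:, [pos[f] for f in kept]]
    if result.transform is not None:
        X = result.transform.apply(X, kept)
    return X, list(kept)


def filter_views(
    data: MultiViewData,
    method: str = "linear",
    supervised: bool = True,
    log2: bool = False,
    center: bool = False,
    scale: bool = False,
    normalize: bool = False,
    padjust: bool = True,
    adjmethod: str = "BH",
    alpha: float = 0.05,
    keep_fraction: float = 0.5,
) -> tuple[MultiViewData, list[FilterResult]]:
    """Preprocess + filter every view of a training MultiViewData."""
    new_views, new_names, results = [], [], []
    for X, vname, feats in zip(data.views, data.view_names, data.feature_names):
        Xt, rec = preprocess(X, log2=log2, center=center, scale=scale, normalize=normalize,
                             feature_names=feats, on_zero_variance="drop")
        if supervised:
            res = supervised_filter(Xt, feats, data.outcome, method=method,
                                    padjust=padjust, adjmethod=adjmethod, alpha=alpha,
                                    view_name=vname, transform=rec)
        else:
            res = unsupervised_filter(Xt, feats, method=method,
                                      keep_fraction=keep_fraction,
                                      view_name=vname, transform=rec)
        keep_idx = res.table.index[res.table["keep"]].to_numpy()
        new_views.append(Xt[:, keep_idx])
        new_names.append(res.kept_features)
        results.append(res)
    return data.with_views(new_views, new_names), results
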