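"""Outcome models on learned canonical variates, prediction and metrics.

Canonical variates (and optional unpenalized covariates) enter a GLM with the
canonical link (gaussian/binomial/poisson) or a Cox proportional-hazards
model (survival, Efron ties).  Performance reporting covers the binomial and
gaussian families only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import Outcome
from .exceptions import ValidationError
from .selpcca import SelpccaModel
from .serialize import register_model

FAMILIES = ("gaussian", "binomial", "poisson", "survival")

_FAMILY_KINDS = {
    "gaussian": ("continuous",),
    "binomial": ("binary",),
    "poisson": ("count", "continuous"),
    "survival": ("survival",),
}


@register_model
@dataclass
class OutcomeModel:
    """GLM or Cox model over canonical variates U_1..U_K, V_1..V_K."""

    family: str
    terms: list[str]  # predictor names, excluding the intercept
    params: np.ndarray  # aligned with coef_table rows
    coef_table: pd.DataFrame  # term, estimate, std_error, statistic, p_value
    has_intercept: bool
    class_labels: np.ndarray | None = None  # binomial: labels[1] is "success"
    selpcca_model: SelpccaModel | None = None

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        missing = [t for t in self.terms if t not in design.columns]
        if missing:
            raise ValidationError(f"missing model terms: {missing}")
        X = design[self.terms].to_numpy(dtype=float)
        eta = X @ self.params[1:] + self.params[0] if self.has_intercept \
            else X @ self.params
        return eta


@dataclass
class PerformanceReport:
    """Prediction metrics; which fields are set depends on the family."""

    family: str
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    npv: float | None = None
    f1: float | None = None
    auc: float | None = None
    mse: float | None = None
    rmse: float | None = None
    mae: float | None = None
    r2: float | None = None
    correlation: float | None = None

    def to_dict(self) -> dict:
        keys = {
            "binomial": ("accuracy", "sensitivity", "specificity", "precision",
                         "npv", "f1", "auc"),
            "gaussian": ("mse", "rmse", "mae", "r2", "correlation"),
        }[self.family]
        return {"family": self.family, **{k: getattr(self, k) for k in keys}}


def scores_frame(U: np.ndarray, V: np.ndarray,
                 covariates: np.ndarray | None = None,
                 covariate_names: list[str] | None = None) -> pd.DataFrame:
    """Assemble the outcome-model design frame from per-view score matrices."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[0] == 1 and V.shape[0] == 1 and U.shape[1] > 1:
        U, V = U.T, V.T
    cols = {f"U_{k + 1}": U[:, k] for k in range(U.shape[1])}
    cols.update({f"V_{k + 1}": V[:, k] for k in range(V.shape[1])})
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] == 1 and covariates.shape[1] == U.shape[0]:
            covariates = covariates.T
        names = covariate_names or [f"cov_{j + 1}" for j in range(covariates.shape[1])]
        cols.update({nm: covariates[:, j] for j, nm in enumerate(names)})
    return pd.DataFrame(cols)


def fit_outcome_model(
    scores: pd.DataFrame,
    outcome: Outcome,
    family: str,
    selpcca_model: SelpccaModel | None = None,
) -> OutcomeModel:
    """Fit the outcome model by maximum (partial) likelihood.

    ``scores`` is a design frame (e.g. from :func:`scores_frame`).  Survival
    fits have no intercept; all other families include one.
    """
    import statsmodels.api as sm

    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    if outcome.kind not in _FAMILY_KINDS[family]:
        raise ValidationError(
            f"family {family!r} incompatible with outcome kind {outcome.kind!r}"
        )
    terms = list(scores.columns)
    n = len(scores)
    if outcome.n != n:
        raise ValidationError("outcome length does not match score rows")
    if family != "survival" and n <= len(terms) + 1:
        raise ValidationError("need more samples than model terms")

    class_labels = None
    if family == "survival":
        from lifelines import CoxPHFitter

        df = scores.copy()
        df["__time__"] = outcome.time
        df["__event__"] = outcome.event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="__time__", event_col="__event__")
        summ = cph.summary
        table = pd.DataFrame({
            "term": terms,
            "estimate": summ.loc[terms, "coef"].to_numpy(),
            "std_error": summ.loc[terms, "se(coef)"].to_numpy(),
            "statistic": summ.loc[terms, "z"].to_numpy(),
            "p_value": summ.loc[terms, "p"].to_numpy(),
        })
        params = table["estimate"].to_numpy()
        return OutcomeModel(family=family, terms=terms, params=params,
                            coef_table=table, has_intercept=False,
                            selpcca_model=selpcca_model)

    if family == "binomial":
        class_labels = outcome.classes
        y = (np.asarray(outcome.values) == class_labels[1]).astype(float)
        sm_family = sm.families.Binomial()
    elif family == "poisson":
        y = np.asarray(outcome.values, dtype=float)
        sm_family = sm.families.Poisson()
    else:
        y = np.asarray(outcome.values, dtype=float)
        sm_family = sm.families.Gaussian()

    X = sm.add_constant(scores.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm_family).fit(maxiter=100)
    if not np.all(np.isfinite(res.params)):
        raise ValidationError("outcome model produced non-finite coefficients")
    if not np.all(np.isfinite(res.bse)):
        warnings.warn("outcome model standard errors are unstable "
                      "(possible separation)", stacklevel=2)
    names = ["(Intercept)"] + terms
    table = pd.DataFrame({
        "term": names,
        "estimate": res.params,
        "std_error": res.bse,
        "statistic": res.tvalues,
        "p_value": res.pvalues,
    })
    return OutcomeModel(family=family, terms=terms, params=res.params,
                        coef_table=table, has_intercept=True,
                        class_labels=class_labels, selpcca_model=selpcca_model)


def predict_outcome(model: OutcomeModel, new_scores: pd.DataFrame) -> np.ndarray:
    """Predictions on the response scale: mean (gaussian), probability
    (binomial), expected count (poisson) or relative log-risk (survival)."""
    eta = model.linear_predictor(new_scores)
    if model.family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if model.family == "poisson":
        return np.exp(eta)
    return eta  # gaussian mean, or survival linear predictor


def _auc_mann_whitney(pred: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(pred)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def performance_metrics(
    predicted: np.ndarray,
    truth: np.ndarray,
    family: str,
    threshold: float = 0.5,
) -> PerformanceReport:
    """Binomial: confusion-matrix rates at ``threshold`` plus rank-based AUC.
    Gaussian: MSE/RMSE/MAE/R^2/Pearson correlation."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValidationError("predicted and truth lengths differ")
    if family == "binomial":
        if not np.all(np.isin(truth, (0.0, 1.0))):
            raise ValidationError("binomial truth must be 0/1")
        labels = (predicted >= threshold).astype(float)
        tp = float(np.sum((labels == 1) & (truth == 1)))
        tn = float(np.sum((labels == 0) & (truth == 0)))
        fp = float(np.sum((labels == 1) & (truth == 0)))
        fn = float(np.sum((labels == 0) & (truth == 1)))

        def rate(num, den):
            return num / den if den > 0 else None

        sens = rate(tp, tp + fn)
        prec = rate(tp, tp + fp)
        if prec in (None, 0) and sens in (None, 0):
            f1 = 0.0
        elif prec is None or sens is None or prec + sens == 0:
            f1 = 0.0
        else:
            f1 = 2 * prec * sens / (prec + sens)
        if len(np.unique(truth)) < 2:
            warnings.warn("single-class truth: AUC undefined", stacklevel=2)
            auc = None
        else:
            auc = _auc_mann_whitney(predicted, truth)
        return PerformanceReport(
            family="binomial",
            accuracy=(tp + tn) / len(truth),
            sensitivity=sens,
            specificity=rate(tn, tn + fp),
            precision=prec,
            npv=rate(tn, tn + fn),
            f1=f1,
            auc=auc,
        )
    if family == "gaussian":
        resid = predicted - truth
        mse = float(np.mean(resid**2))
        sst = float(np.sum((truth - truth.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else None
        corr = (float(np.corrcoef(predicted, truth)[0, 1])
                if predicted.std() > 0 and truth.std() > 0 else None)
        return PerformanceReport(
            family="gaussian",
            mse=mse,
            rmse=float(np.sqrt(mse)),
            mae=float(np.mean(np.abs(resid))),
            r2=r2,
            correlation=corr,
        )
    raise ValidationError("performance metrics support 'binomial' and 'gaussian' only")
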