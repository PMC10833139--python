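"""Data containers, delimited-table I/O, sample alignment and train/test splitting.

All matrices are oriented samples x features.  Input tables are CSV/TSV with a
header row of feature names and a first column of sample identifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError, ValidationError

logger = logging.getLogger(__name__)

OUTCOME_KINDS = ("binary", "multiclass", "continuous", "count", "survival")


@dataclass
class Outcome:
    """Clinical outcome attached to a :class:`MultiViewData`.

    Parameters
    ----------
    kind : str
        One of ``binary``, ``multiclass``, ``continuous``, ``count``,
        ``survival``.
    values : ndarray, optional
        Length-``n`` label/value vector (all kinds except ``survival``).
    time, event : ndarray, optional
        Positive survival times and 0/1 event indicators (``survival`` only).
    """

    kind: str
    values: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in OUTCOME_KINDS:
            raise ValidationError(f"unknown outcome kind {self.kind!r}")
        if self.kind == "survival":
            if self.time is None or self.event is None:
                raise ValidationError("survival outcome requires time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=float)
            if self.time.shape != self.event.shape:
                raise ValidationError("time and event lengths differ")
            if np.any(self.time <= 0):
                raise ValidationError("survival times must be positive")
            if not np.all(np.isin(self.event, (0.0, 1.0))):
                raise ValidationError("event indicator must be 0/1")
        else:
            if self.values is None:
                raise ValidationError(f"{self.kind} outcome requires values")
            self.values = np.asarray(self.values)
            k = len(np.unique(self.values))
            if self.kind == "binary" and k != 2:
                raise ValidationError(f"binary outcome has {k} distinct labels")
            if self.kind == "multiclass" and k < 2:
                raise ValidationError("multiclass outcome needs >= 2 classes")
            if self.kind == "count":
                v = np.asarray(self.values, dtype=float)
                if np.any(v < 0) or np.any(v != np.round(v)):
                    raise ValidationError("count outcome must be nonnegative integers")

    @property
    def n(self) -> int:
        return len(self.time) if self.kind == "survival" else len(self.values)

    @property
    def classes(self) -> np.ndarray:
        if self.kind not in ("binary", "multiclass"):
            raise ValidationError(f"{self.kind} outcome has no classes")
        return np.unique(self.values)

    def subset(self, idx: np.ndarray) -> "Outcome":
        # no re-validation: a subset of a binary outcome may lose a class
        out = object.__new__(Outcome)
        out.kind = self.kind
        if self.kind == "survival":
            out.values, out.time, out.event = None, self.time[idx], self.event[idx]
        else:
            out.values, out.time, out.event = self.values[idx], None, None
        return out


@dataclass
class MultiViewData:
    """Aligned collection of >= 2 feature matrices plus optional outcome.

    Invariants (checked on construction): identical row count and sample order
    across views, unique feature names per view, no missing values.
    """

    views: list[np.ndarray]
    view_names: list[str]
    feature_names: list[list[str]]
    sample_ids: list[str]
    outcome: Outcome | None = None
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.views = [np.asarray(v, dtype=float) for v in self.views]
        n = len(self.sample_ids)
        for name, v, feats in zip(self.view_names, self.views, self.feature_names):
            if v.ndim != 2:
                raise ValidationError(f"view {name!r} is not a matrix")
            if v.shape[0] != n:
                raise ValidationError(
                    f"view {name!r} has {v.shape[0]} rows, expected {n}"
                )
            if v.shape[1] != len(feats):
                raise ValidationError(f"view {name!r} feature-name count mismatch")
            if len(set(feats)) != len(feats):
                dupes = sorted({f for f in feats if feats.count(f) > 1})
                raise ValidationError(f"duplicate feature names in {name!r}: {dupes}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"view {name!r} contains missing/non-finite values")
        if self.outcome is not None and self.outcome.n != n:
            raise ValidationError("outcome length does not match sample count")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != n:
                raise ValidationError("covariate row count mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    def subset(self, idx: np.ndarray) -> "MultiViewData":
        """Row subset (by positional indices), preserving order of ``idx``."""
        idx = np.asarray(idx)
        return MultiViewData(
            views=[v[idx] for v in self.views],
            view_names=list(self.view_names),
            feature_names=[list(f) for f in self.feature_names],
            sample_ids=[self.sample_ids[i] for i in idx],
            outcome=self.outcome.subset(idx) if self.outcome is not None else None,
            covariates=self.covariates[idx] if self.covariates is not None else None,
            covariate_names=list(self.covariate_names),
        )

    def with_views(self, views: list[np.ndarray], feature_names: list[list[str]]) -> "MultiViewData":
        return replace(self, views=views, feature_names=feature_names)


def _read_table(path: str, delimiter: str | None = None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(delimiter)[1:]
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not read table {path}: {exc}") from exc
    if len(set(header)) != len(header):  # pandas silently mangles duplicates
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate feature names in {path}: {dupes}")
    df.index = df.index.astype(str)
    return df


def _numeric_or_error(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(
            f"non-numeric cell in {path} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if out.isna().any().any():
        r, c = np.argwhere(out.isna().values)[0]
        raise ParseError(
            f"missing value in {path} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def _parse_outcome(df: pd.DataFrame, kind: str | None) -> Outcome:
    cols = [c.lower() for c in df.columns]
    if kind == "survival" or ("time" in cols and "event" in cols):
        t = df.iloc[:, cols.index("time")].to_numpy(dtype=float)
        e = df.iloc[:, cols.index("event")].to_numpy(dtype=float)
        return Outcome("survival", time=t, event=e)
    values = df.iloc[:, 0].to_numpy()
    if kind is None:
        uniq = np.unique(values)
        if len(uniq) == 2:
            kind = "binary"
        elif values.dtype.kind in "OUS" or len(uniq) <= max(10, int(0.05 * len(values))):
            kind = "multiclass"
        else:
            kind = "continuous"
    return Outcome(kind, values=values)


def load_views(
    paths: list[str],
    outcome_path: str | None = None,
    covariate_path: str | None = None,
    delimiter: str | None = None,
    view_names: list[str] | None = None,
    outcome_kind: str | None = None,
) -> MultiViewData:
    """Load delimited view tables, align samples and assemble a MultiViewData.

    Rows are intersected across all tables and reordered to the sample order
    of the first view; dropped samples are reported via a warning.
    """
    if len(paths) < 1:
        raise ValidationError("at least one view path required")
    if view_names is None:
        view_names = [f"view{i + 1}" for i in range(len(paths))]
    frames = []
    for p in paths:
        df = _read_table(p, delimiter)
        if df.columns.duplicated().any():
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate feature names in {p}: {dupes}")
        frames.append(_numeric_or_error(df, str(p)))
    outcome_df = cov_df = None
    if outcome_path is not None:
        outcome_df = _read_table(outcome_path, delimiter)
    if covariate_path is not None:
        cov_df = _numeric_or_error(_read_table(covariate_path, delimiter), str(covariate_path))

    common = list(frames[0].index)
    all_ids: set[str] = set(common)
    for df in frames[1:]:
        all_ids |= set(df.index)
        keep = set(df.index)
        common = [s for s in common if s in keep]
    for df in (outcome_df, cov_df):
        if df is not None:
            all_ids |= set(df.index)
            keep = set(df.index)
            common = [s for s in common if s in keep]
    if not common:
        raise AlignmentError("no sample identifiers shared by all tables")
    dropped = sorted(all_ids - set(common))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} samples absent from some table: {dropped}",
            stacklevel=2,
        )
        logger.info("dropped samples: %s", dropped)

    views = [df.loc[common].to_numpy(dtype=float) for df in frames]
    outcome = _parse_outcome(outcome_df.loc[common], outcome_kind) if outcome_df is not None else None
    covariates = cov_df.loc[common].to_numpy(dtype=float) if cov_df is not None else None
    return MultiViewData(
        views=views,
        view_names=view_names,
        feature_names=[list(df.columns) for df in frames],
        sample_ids=common,
        outcome=outcome,
        covariates=covariates,
        covariate_names=list(cov_df.columns) if cov_df is not None else [],
    )


def save_views(data: MultiViewData, out_dir, prefix: str = "") -> dict[str, str]:
    """Write each view (and outcome/covariates) as CSV; returns written paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for name, X, feats in zip(data.view_names, data.views, data.feature_names):
        path = os.path.join(out_dir, f"{prefix}{name}.csv")
        pd.DataFrame(X, index=data.sample_ids, columns=feats).to_csv(path, index_label="sample_id")
        written[name] = path
    if data.outcome is not None:
        path = os.path.join(out_dir, f"{prefix}outcome.csv")
        o = data.outcome
        if o.kind == "survival":
            df = pd.DataFrame({"time": o.time, "event": o.event}, index=data.sample_ids)
        else:
            df = pd.DataFrame({"outcome": o.values}, index=data.sample_ids)
        df.to_csv(path, index_label="sample_id")
        written["outcome"] = path
    if data.covariates is not None:
        path = os.path.join(out_dir, f"{prefix}covariates.csv")
        pd.DataFrame(
            data.covariates, index=data.sample_ids, columns=data.covariate_names
        ).to_csv(path, index_label="sample_id")
        written["covariates"] = path
    return written


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_train_test(
    data: MultiViewData,
    pct_train: float,
    stratify: bool = False,
    seed: int | None = None,
) -> tuple[MultiViewData, MultiViewData]:
    """Random disjoint, exhaustive train/test split of all views at once.

    With ``stratify`` (requires a class-valued outcome), per-class train counts
    are ``round(pct_train * n_k)`` with half rounded away from zero; any
    deficit/excess relative to the overall target is adjusted on the largest
    class, and each class keeps at least one test sample when it has >= 2.
    """
    if not 0 < pct_train < 1:
        raise ValidationError("pct_train must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n_samples

    if stratify:
        if data.outcome is None or data.outcome.kind not in ("binary", "multiclass"):
            raise ValidationError("stratified split requires a class-valued outcome")
        y = np.asarray(data.outcome.values)
        classes, counts = np.unique(y, return_counts=True)
        targets = {}
        for cls, n_k in zip(classes, counts):
            if n_k == 1:
                warnings.warn(
                    f"class {cls!r} has a single sample; assigned to the training set",
                    stacklevel=2,
                )
                targets[cls] = 1
                continue
            t = _round_half_away(pct_train * n_k)
            targets[cls] = min(max(t, 1), n_k - 1)
        total_target = _round_half_away(pct_train * n)
        largest = classes[np.argmax(counts)]
        n_largest = counts[np.argmax(counts)]
        diff = total_target - sum(targets.values())
        if diff:
            adjusted = targets[largest] + diff
            targets[largest] = min(max(adjusted, 1), max(n_largest - 1, 1))
        train_idx = []
        for cls in classes:
            members = np.flatnonzero(y == cls)
            perm = rng.permutation(members)
            train_idx.extend(perm[: targets[cls]])
        train_idx = np.sort(np.asarray(train_idx))
    else:
        n_train = min(max(_round_half_away(pct_train * n), 1), n - 1)
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])

    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    return data.subset(train_idx), data.subset(test_idx)
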