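"""RBF-kernel support-vector classification with SN/SP/ACC reporting.

The classifier is an RBF-kernel SVM with C = 128 and gamma = 0.5, the values
found by grid optimisation in the original study of this pipeline; both are
overridable and a :func:`grid_search` helper re-runs the optimisation.
Features are min-max scaled with statistics from the training split only —
cross-validation refits the scaler inside every fold so no test-fold range
information leaks into training.

Metric conventions (all percentages):

* SN  = 100 * TP / (TP + FN)
* SP  = 100 * TN / (TN + FP)   (the standard specificity; a legacy
  ``sp_formula="printed"`` variant computes 100 * TP / (TN + FP) as some
  older reports of this method print it)
* ACC = 100 * (TP + TN) / (TP + TN + FP + FN)

A zero denominator yields ``nan`` ("undefined"), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .ctd import DomainError
from .seqio import FeatureTable

DEFAULT_C = 128.0
DEFAULT_GAMMA = 0.5
DEFAULT_FOLDS = 10


@dataclass
class MinMaxScaler:
    """Per-feature min-max scaling to [0, 1]; zero-range columns map to 0.5."""

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins=mins, ranges=ranges)

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = np.empty_like(X, dtype=float)
        zero = self.ranges == 0
        nz = ~zero
        out[:, nz] = (X[:, nz] - self.mins[nz]) / self.ranges[nz]
        out[:, zero] = 0.5
        return out


@dataclass
class TrainedModel:
    """A fitted scaler + SVC pair bound to its feature names."""

    svc: SVC
    scaler: MinMaxScaler
    feature_names: list[str]
    c: float
    gamma: float

    def _align(self, table: FeatureTable) -> np.ndarray:
        if table.feature_names == self.feature_names:
            return table.values
        index = {n: i for i, n in enumerate(table.feature_names)}
        missing = [n for n in self.feature_names if n not in index]
        if missing:
            raise DomainError(f"table is missing model features {missing[:5]!r}")
        return table.values[:, [index[n] for n in self.feature_names]]

    def decision_values(self, table: FeatureTable) -> np.ndarray:
        X = self.scaler.transform(self._align(table))
        return self.svc.decision_function(X)

    def predict(self, table: FeatureTable) -> np.ndarray:
        """Predicted binary labels (positive=1) from the signed margin."""
        return (self.decision_values(table) > 0).astype(int)

    def negative_support_row_indices(self, train_table: FeatureTable) -> np.ndarray:
        """Row indices (into the training table) of negative-class support vectors."""
        y = train_table.y()
        sv = self.svc.support_
        return sv[y[sv] == 0]


def train(
    table: FeatureTable,
    c: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> TrainedModel:
    """Fit the RBF-SVM on a labeled table (min-max scaling from the table)."""
    y = table.y()
    if len(np.unique(y)) < 2:
        raise DomainError("training table must contain both classes")
    if not np.all(np.isfinite(table.values)):
        raise DomainError("training features must be finite")
    scaler = MinMaxScaler.fit(table.values)
    svc = SVC(kernel="rbf", C=c, gamma=gamma)
    svc.fit(scaler.transform(table.values), y)
    return TrainedModel(
        svc=svc, scaler=scaler, feature_names=list(table.feature_names),
        c=c, gamma=gamma,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    confusion: tuple[int, int, int, int],
    sp_formula: str = "standard",
) -> tuple[float, float, float]:
    """(SN, SP, ACC) percentages from (TP, TN, FP, FN) counts.

    Undefined ratios (zero denominator) come back as ``nan``.
    """
    tp, tn, fp, fn = confusion
    if min(tp, tn, fp, fn) < 0:
        raise DomainError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise DomainError("empty confusion table")
    sn = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else math.nan
    if sp_formula == "standard":
        sp = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else math.nan
    elif sp_formula == "printed":
        sp = 100.0 * tp / (tn + fp) if (tn + fp) > 0 else math.nan
    else:
        raise ValueError(f"unknown sp_formula {sp_formula!r}")
    acc = 100.0 * (tp + tn) / total
    return sn, sp, acc


@dataclass
class CVMetrics:
    """Per-fold and pooled confusion counts with derived SN/SP/ACC."""

    per_fold: list[tuple[int, int, int, int]]
    sp_formula: str = "standard"

    @property
    def aggregate(self) -> tuple[int, int, int, int]:
        agg = np.array(self.per_fold).sum(axis=0)
        return tuple(int(x) for x in agg)

    @property
    def sn(self) -> float:
        return compute_metrics(self.aggregate, self.sp_formula)[0]

    @property
    def sp(self) -> float:
        return compute_metrics(self.aggregate, self.sp_formula)[1]

    @property
    def acc(self) -> float:
        return compute_metrics(self.aggregate, self.sp_formula)[2]

    def summary(self) -> dict:
        tp, tn, fp, fn = self.aggregate
        return {
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "SN": self.sn, "SP": self.sp, "ACC": self.acc,
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, tn, fp, fn


def cross_validate(
    table: FeatureTable,
    folds: int = DEFAULT_FOLDS,
    c: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> CVMetrics:
    """Stratified k-fold CV; scaler and SVM refit per fold on the train split."""
    y = table.y()
    if folds < 2:
        raise DomainError("folds must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise DomainError(
            f"each class needs >= {folds} rows for {folds}-fold CV "
            f"(got {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    X = table.values
    for train_idx, test_idx in skf.split(X, y):
        scaler = MinMaxScaler.fit(X[train_idx])
        svc = SVC(kernel="rbf", C=c, gamma=gamma)
        svc.fit(scaler.transform(X[train_idx]), y[train_idx])
        pred = (svc.decision_function(scaler.transform(X[test_idx])) > 0).astype(int)
        per_fold.append(_confusion(y[test_idx], pred))
    return CVMetrics(per_fold=per_fold)


def grid_search(
    table: FeatureTable,
    c_grid,
    gamma_grid,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
):
    """Exhaustive CV over the (C, gamma) grid; argmax ACC.

    Ties prefer smaller C, then smaller gamma. Returns
    (best_c, best_gamma, CVMetrics, trace) where trace lists
    (c, gamma, acc) for every grid point.
    """
    c_grid = list(c_grid)
    gamma_grid = list(gamma_grid)
    if not c_grid or not gamma_grid:
        raise DomainError("grids must be non-empty")
    best = None
    trace = []
    for c in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            metrics = cross_validate(table, folds=folds, c=c, gamma=gamma, seed=seed)
            trace.append((c, gamma, metrics.acc))
            if best is None or metrics.acc > best[2].acc:
                best = (c, gamma, metrics)
    return best[0], best[1], best[2], trace
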