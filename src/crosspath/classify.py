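"""L1-regularized linear SVM with pooled-LOOCV hyperparameter selection.

The classifier minimizes an L1-penalized squared-hinge objective

    ||w||_1 + |b| + C * sum_i cw(y_i) * max(0, 1 - y~_i (w.x_i + b))^2

with y~ in {-1, +1} and balanced class weights cw(y) = n_total / (2 n_y),
via scikit-learn's ``LinearSVC`` (liblinear primal solver; the intercept is
part of the penalized coefficient vector in that solver, which is the
convention kept here).  The penalty C is chosen by leave-one-out
cross-validation: held-out predictions are pooled over folds into a single
F1 score per grid value, and ties resolve to the smallest C (sparsest
model).  The L1 penalty doubles as feature selection: features with nonzero
weight are the ones the classifier actually uses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

__all__ = [
    "LinearL1SVM",
    "CVReport",
    "ClassificationMetrics",
    "fit_l1_svm",
    "select_C",
    "predict",
    "evaluate",
    "nonzero_features",
    "default_c_grid",
]


def default_c_grid(n_points: int = 50) -> np.ndarray:
    """Log-spaced C grid spanning 1e-3 .. 1e2."""
    return np.logspace(-3, 2, n_points)


@dataclass
class LinearL1SVM:
    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    C: float
    class_weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != len(self.weights):
            raise ValueError("feature-name count must equal weight length")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.intercept)):
            raise ValueError("non-finite model parameters")

    def to_json(self, path) -> None:
        payload = {
            "features": self.feature_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "LinearL1SVM":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["features"],
            weights=np.asarray(d["weights"], dtype=float),
            intercept=d["intercept"],
            C=d["C"],
            class_weights={int(k): v for k, v in d["class_weights"].items()},
        )


@dataclass
class CVReport:
    grid: np.ndarray
    pooled_f1: np.ndarray
    chosen_C: float
    tie_note: str = ""

    def to_dict(self) -> dict:
        return {
            "grid": [float(c) for c in self.grid],
            "pooled_f1": [float(f) for f in self.pooled_f1],
            "chosen_C": float(self.chosen_C),
            "tie_note": self.tie_note,
        }


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    f1: float
    auc: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
        }


def _balanced_weights(y: np.ndarray) -> dict[int, float]:
    n = len(y)
    return {int(c): n / (2.0 * int(np.sum(y == c))) for c in (0, 1)}


def _feature_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X, [str(i) for i in range(X.shape[1])]


def fit_l1_svm(X, y, C: float) -> LinearL1SVM:
    """Fit the L1 squared-hinge linear SVM with balanced class weights."""
    Xm, names = _feature_matrix(X)
    y = np.asarray(y, dtype=int)
    if C <= 0:
        raise ValueError("C must be positive")
    if not np.isfinite(Xm).all():
        raise ValueError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cw = _balanced_weights(y)
    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=C,
        class_weight=cw,
        tol=1e-6,
        max_iter=100_000,
        random_state=0,
    )
    # inputs were validated above; skip sklearn's per-fit re-validation
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        clf.fit(Xm, y)
    return LinearL1SVM(
        feature_names=names,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        C=float(C),
        class_weights=cw,
    )


def select_C(X, y, grid=None) -> CVReport:
    """Pooled-LOOCV F1 maximization over a C grid; ties -> smallest C."""
    Xm, _ = _feature_matrix(X)
    y = np.asarray(y, dtype=int)
    grid = np.sort(np.asarray(list(grid if grid is not None else default_c_grid()), dtype=float))
    if len(grid) == 0:
        raise ValueError("empty C grid")
    n = len(y)
    f1s = []
    for C in grid:
        truths, preds = [], []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < 2:
                logger.warning("LOOCV fold %d skipped: training fold single-class", i)
                continue
            model = fit_l1_svm(Xm[mask], y[mask], C)
            pred, _ = predict(model, Xm[i][None, :])
            truths.append(y[i])
            preds.append(int(pred[0]))
        if not truths:
            raise ValueError("all LOOCV folds degenerate")
        f1s.append(f1_score(truths, preds, pos_label=1, zero_division=0))
    f1s = np.asarray(f1s)
    best = float(np.max(f1s))
    winners = grid[f1s == best]
    chosen = float(winners[0])
    note = ""
    if len(winners) > 1:
        note = f"{len(winners)} grid values tied at F1={best:.4f}; smallest C kept"
    return CVReport(grid=grid, pooled_f1=f1s, chosen_C=chosen, tie_note=note)


def predict(model: LinearL1SVM, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values; the boundary d = 0 maps to class 0."""
    if isinstance(X, pd.DataFrame):
        if [str(c) for c in X.columns] != model.feature_names:
            raise ValueError("feature-name mismatch")
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if Xm.shape[1] != len(model.feature_names):
            raise ValueError("feature-count mismatch")
    decisions = Xm @ model.weights + model.intercept
    labels = (decisions > 0).astype(int)
    return labels, decisions


def evaluate(y_true, y_pred, decisions=None) -> ClassificationMetrics:
    """Confusion counts (positive = diseased), accuracy, F1 and rank AUC."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / len(y_true)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    auc = None
    if decisions is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, np.asarray(decisions, dtype=float)))
    return ClassificationMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy, f1=f1, auc=auc)


def nonzero_features(model: LinearL1SVM, tol: float = 1e-8) -> set[str]:
    """Feature names the classifier actually uses (|w| > tol)."""
    return {n for n, w in zip(model.feature_names, model.weights) if abs(w) > tol}
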