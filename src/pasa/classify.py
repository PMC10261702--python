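"""RBF-kernel SVM classification of tissue type from relative-APSD features.

A C-type support vector machine with the radial basis function kernel

    K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2),  gamma > 0,

is trained under stratified three-fold cross-validation: per outer fold the
(C, gamma) pair is chosen by an inner grid search with cross-validation,
features are z-scored on the training fold, and test predictions are pooled
into a confusion matrix (predicted labels on rows, true labels on columns)
with per-class accuracies and one-vs-rest ROC/AUC from decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "SVMConfig",
    "CVReport",
    "PredictionEvaluation",
    "rbf_kernel",
    "grid_search",
    "threefold_cv",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameter search space and protocol options for the SVM."""

    C_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4))
    seed: int = 0
    standardize: bool = True
    n_folds: int = 3
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")


def rbf_kernel(x_i, x_j, gamma: float) -> float:
    """exp(-gamma * ||x_i - x_j||^2); equals 1 iff the vectors coincide."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = np.asarray(x_i, float)
    b = np.asarray(x_j, float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.exp(-gamma * np.sum((a - b) ** 2)))


def _accuracy(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def grid_search(train_features, train_labels, config: SVMConfig | None = None
                ) -> tuple[float, float]:
    """Pick (C, gamma) maximizing inner-CV accuracy on the training fold.

    Ties are broken toward the smallest C, then the smallest gamma (prefer
    the simpler, smoother model).
    """
    if config is None:
        config = SVMConfig()
    X = np.asarray(train_features, float)
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search needs at least two classes in the training data")
    n_inner = int(min(config.inner_folds, counts.min()))
    if n_inner < 2:
        raise ValueError("each class needs at least 2 training samples for inner CV")
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=config.seed)
    C_grid = sorted(config.C_grid)
    g_grid = sorted(config.gamma_grid)
    scores = np.zeros((len(C_grid), len(g_grid)))
    for tr, te in skf.split(X, y):
        X_tr, X_te = X[tr], X[te]
        if config.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        for i, C in enumerate(C_grid):
            for j, g in enumerate(g_grid):
                clf = SVC(C=C, gamma=g, kernel="rbf").fit(X_tr, y[tr])
                scores[i, j] += _accuracy(y[te], clf.predict(X_te))
    best, best_score = (C_grid[0], g_grid[0]), -np.inf
    for i, C in enumerate(C_grid):
        for j, g in enumerate(g_grid):
            if scores[i, j] > best_score:  # strict: first (smallest) wins ties
                best, best_score = (C, g), scores[i, j]
    return best


@dataclass
class CVReport:
    """Everything the cross-validated classifier produced."""

    class_order: tuple
    fold_index: np.ndarray  # fold assignment per sample
    train_accuracies: list[float]  # percent, per fold
    test_accuracies: list[float]
    selected_params: list[tuple[float, float]]
    confusion: np.ndarray  # predicted rows x true columns, pooled counts
    per_class_accuracy: np.ndarray  # percent, per true class
    roc: dict  # class -> {"fpr", "tpr", "auc"}

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean(self.train_accuracies))

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean(self.test_accuracies))

    def summary_text(self) -> str:
        lines = ["fold  train%  test%   C        gamma"]
        for k, (tr, te, (C, g)) in enumerate(
                zip(self.train_accuracies, self.test_accuracies, self.selected_params)):
            lines.append(f"{k + 1:>4}  {tr:6.1f}  {te:5.1f}   {C:<8g} {g:g}")
        lines.append(f"mean  {self.mean_train_accuracy:6.1f}  {self.mean_test_accuracy:5.1f}")
        lines.append("")
        lines.append("confusion matrix (rows: predicted, cols: true "
                     + "/".join(map(str, self.class_order)) + ")")
        for row in self.confusion:
            lines.append("  " + "  ".join(f"{int(v):3d}" for v in row))
        lines.append("per-class accuracy (%): "
                     + "  ".join(f"{c}: {a:.1f}" for c, a in
                                 zip(self.class_order, self.per_class_accuracy)))
        lines.append("AUC: " + "  ".join(f"{c}: {self.roc[c]['auc']:.2f}"
                                         for c in self.class_order))
        return "\n".join(lines)


def threefold_cv(feature_matrix: FeatureMatrix, config: SVMConfig | None = None,
                 feature_wavelengths: Sequence[float] | None = None,
                 class_order: Sequence | None = None) -> CVReport:
    """Stratified k-fold (default 3) CV with per-fold grid search.

    ``feature_wavelengths`` restricts the input to a subset of feature
    columns, e.g. ``[1210.0]`` for the single-wavelength classifier; the
    default uses all 21 features.
    """
    if config is None:
        config = SVMConfig()
    if feature_wavelengths is None:
        X = feature_matrix.features
    else:
        X = np.column_stack([feature_matrix.column(w) for w in feature_wavelengths])
    y = np.asarray(feature_matrix.labels)
    if class_order is None:
        class_order = tuple(sorted(np.unique(y)))
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"every class needs >= {config.n_folds} samples for {config.n_folds}-fold CV")

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    n = X.shape[0]
    fold_index = np.full(n, -1)
    train_acc, test_acc, params = [], [], []
    pooled_true, pooled_pred = [], []
    pooled_scores = np.zeros((n, len(class_order)))
    for k, (tr, te) in enumerate(skf.split(X, y)):
        fold_index[te] = k
        X_tr, X_te = X[tr], X[te]
        if config.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        C, g = grid_search(X_tr, y[tr], config)
        clf = SVC(C=C, gamma=g, kernel="rbf",
                  decision_function_shape="ovr").fit(X_tr, y[tr])
        params.append((C, g))
        train_acc.append(100.0 * _accuracy(y[tr], clf.predict(X_tr)))
        pred = clf.predict(X_te)
        test_acc.append(100.0 * _accuracy(y[te], pred))
        pooled_true.extend(y[te])
        pooled_pred.extend(pred)
        scores = clf.decision_function(X_te)
        if scores.ndim == 1:  # binary: expand to two ovr columns
            scores = np.column_stack([-scores, scores])
        order = [list(clf.classes_).index(c) for c in class_order]
        pooled_scores[te] = scores[:, order]

    confusion = _confusion(pooled_true, pooled_pred, class_order)
    per_class = _per_class_accuracy(confusion)
    roc = {}
    y_arr = np.asarray(y)
    for ci, c in enumerate(class_order):
        fpr, tpr, _ = _roc_curve((y_arr == c).astype(int), pooled_scores[:, ci])
        roc[c] = {"fpr": fpr, "tpr": tpr, "auc": float(_auc(fpr, tpr))}
    return CVReport(class_order=tuple(class_order), fold_index=fold_index,
                    train_accuracies=train_acc, test_accuracies=test_acc,
                    selected_params=params, confusion=confusion,
                    per_class_accuracy=per_class, roc=roc)


def _confusion(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Counts with predicted labels on rows and true labels on columns."""
    index = {c: i for i, c in enumerate(class_order)}
    m = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        m[index[p], index[t]] += 1
    return m


def _per_class_accuracy(confusion: np.ndarray) -> np.ndarray:
    col_sums = confusion.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = 100.0 * np.diag(confusion) / col_sums
    return np.where(col_sums > 0, acc, np.nan)


@dataclass(frozen=True)
class PredictionEvaluation:
    confusion: np.ndarray  # predicted rows x true columns
    per_class_accuracy: np.ndarray  # percent per true class
    overall_accuracy: float  # percent
    class_order: tuple


def evaluate_predictions(true_labels: Sequence[int], predicted_labels: Sequence[int],
                         class_order: Sequence = (1, 2, 3)) -> PredictionEvaluation:
    """Confusion matrix, per-class and overall accuracy of a prediction list."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label sequences must have equal length")
    valid = set(class_order)
    bad = [x for x in t + p if x not in valid]
    if bad:
        raise ValueError(f"labels outside {tuple(class_order)}: {sorted(set(bad))}")
    confusion = _confusion(t, p, class_order)
    per_class = _per_class_accuracy(confusion)
    overall = 100.0 * np.trace(confusion) / len(t)
    return PredictionEvaluation(confusion=confusion, per_class_accuracy=per_class,
                                overall_accuracy=float(overall),
                                class_order=tuple(class_order))
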