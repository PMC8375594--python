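"""Nested cross-validated classification.

The outer loop is leave-one-out: for every held-out subject,
z-normalization and feature selection are fitted on the training rows
only (no leakage), the top-k ranked features are kept, and an RBF-SVM is
tuned by an inner stratified 10-fold grid search over
``C, sigma in {4^-4 ... 4^4}`` (81 combinations; the kernel is
``K(x1, x2) = exp(-||x1 - x2||^2 / sigma^2)``).  Ties in inner accuracy
resolve toward the smallest C, then the smallest sigma (smoother models).

Comparator classifiers (random forest, KNN, AdaBoost) run under the same
outer protocol, and ``resample_evaluate`` wraps the whole evaluation in
up-/down-sampling iterations of the training portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .selection import make_selector
from .stats import ClassificationReport, full_report

#: powers of 4 with integer exponents -4..4, for both C and sigma.
PARAM_GRID: np.ndarray = 4.0 ** np.arange(-4, 5)


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """``exp(-||x1 - x2||^2 / sigma^2)``."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-np.sum((x1 - x2) ** 2) / sigma**2))


class GridSearchRBFSVM(ClassifierMixin, BaseEstimator):
    """RBF-SVM with an internal stratified k-fold accuracy grid search.

    ``sigma`` parameterizes the kernel width (sklearn ``gamma = 1/sigma^2``).
    """

    def __init__(
        self,
        C_grid: Sequence[float] | None = None,
        sigma_grid: Sequence[float] | None = None,
        inner_folds: int = 10,
        random_state: int | None = None,
    ):
        self.C_grid = C_grid
        self.sigma_grid = sigma_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        c_grid = np.sort(np.asarray(self.C_grid if self.C_grid is not None else PARAM_GRID))
        s_grid = np.sort(
            np.asarray(self.sigma_grid if self.sigma_grid is not None else PARAM_GRID)
        )
        if c_grid.size == 0 or s_grid.size == 0:
            raise ValueError("parameter grids must be nonempty")
        counts = np.bincount(np.searchsorted(np.unique(y), y))
        n_splits = int(min(self.inner_folds, counts.min()))
        if n_splits < 2:
            raise ValueError("need at least 2 subjects per class for the inner CV")
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.random_state)
        folds = list(cv.split(X, y))

        # squared distances once; one kernel matrix per sigma serves all folds
        sq = np.einsum("ij,ij->i", X, X)
        dist = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
        kernels = {float(sigma): np.exp(-dist / sigma**2) for sigma in s_grid}
        best = (-np.inf, None, None)
        for C in c_grid:  # ascending C, then sigma: ties keep the smaller pair
            for sigma in s_grid:
                kernel = kernels[float(sigma)]
                correct = 0
                for tr, te in folds:
                    model = SVC(C=C, kernel="precomputed")
                    model.fit(kernel[np.ix_(tr, tr)], y[tr])
                    correct += int(np.sum(model.predict(kernel[np.ix_(te, tr)]) == y[te]))
                acc = correct / X.shape[0]
                if acc > best[0]:
                    best = (acc, C, sigma)
        self.inner_score_, self.C_, self.sigma_ = best
        self.model_ = SVC(C=self.C_, gamma=1.0 / self.sigma_**2, kernel="rbf")
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(X)


@dataclass(frozen=True)
class NestedCVConfig:
    """Protocol settings for one nested-CV evaluation."""

    selector: str = "rsfs"          # rsfs | mrmr | sslr | none
    top_k: int = 10
    selector_params: dict = field(default_factory=dict)
    C_grid: tuple[float, ...] = tuple(PARAM_GRID)
    sigma_grid: tuple[float, ...] = tuple(PARAM_GRID)
    inner_folds: int = 10
    selection_scope: str = "per-fold"   # "per-fold" (default) | "global"
    resample: str = "none"              # none | up1 | up2 | down
    resample_iterations: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")
        if self.selector not in ("rsfs", "mrmr", "sslr", "none"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.selection_scope not in ("per-fold", "global"):
            raise ValueError(f"unknown selection scope {self.selection_scope!r}")
        if self.resample not in ("none", "up1", "up2", "down"):
            raise ValueError(f"unknown resample mode {self.resample!r}")


@dataclass
class FoldOutput:
    """Out-of-fold prediction for one held-out subject."""

    held_out_index: int
    true_label: int
    predicted_label: int
    decision_score: float
    C: float | None
    sigma: float | None
    selected_features: tuple[int, ...]


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be 0/1 with 1 the positive class")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of subjects")
    if X.shape[0] < 12:
        raise ValueError("nested CV requires at least 12 subjects")
    return X, y.astype(int)


def _train_scaler(X_train):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _rank_features(X_train, y_train, config: NestedCVConfig, seed: int) -> np.ndarray:
    if config.selector == "none":
        return np.arange(X_train.shape[1])
    selector = make_selector(config.selector, seed=seed, **config.selector_params)
    selector.fit(X_train, y_train)
    return selector.ranking_


def fold_rankings(X, y, config: NestedCVConfig) -> list[np.ndarray]:
    """Per-outer-fold feature rankings, fitted on training rows only.

    With ``selection_scope="global"`` the selector is fitted once on all
    rows and the same ranking reused for every fold (the leakage-prone
    variant, available for comparison).
    """
    X, y = _check_Xy(X, y)
    config.validate()
    n = X.shape[0]
    if config.selection_scope == "global":
        ranking = _rank_features(X, y, config, seed=config.seed)
        return [ranking] * n
    rankings = []
    for i in range(n):
        train = np.arange(n) != i
        if np.unique(y[train]).size < 2:
            raise ValueError("a training fold lost one class entirely")
        mu, sd = _train_scaler(X[train])
        rankings.append(
            _rank_features((X[train] - mu) / sd, y[train], config, seed=config.seed + i)
        )
    return rankings


def _resample_training(X_tr, y_tr, mode: str, rng: np.random.Generator):
    """Equalize class counts in the training portion."""
    if mode == "none":
        return X_tr, y_tr
    idx0 = np.flatnonzero(y_tr == 0)
    idx1 = np.flatnonzero(y_tr == 1)
    minority, majority = (idx0, idx1) if idx0.size < idx1.size else (idx1, idx0)
    if mode == "down":
        if minority.size < 2:
            raise ValueError("minority class too small to down-sample against")
        keep = np.concatenate([minority, rng.choice(majority, size=minority.size, replace=False)])
        return X_tr[keep], y_tr[keep]
    extra = rng.choice(minority, size=majority.size - minority.size, replace=True)
    keep = np.concatenate([np.arange(y_tr.size), extra])
    X_new, y_new = X_tr[keep], y_tr[keep]
    if mode == "up2":  # jittered duplicates: 5% of per-feature SD
        sd = X_tr.std(axis=0)
        jitter = rng.standard_normal((extra.size, X_tr.shape[1])) * 0.05 * sd
        X_new = X_new.copy()
        X_new[y_tr.size :] += jitter
    return X_new, y_new


def _make_comparator(kind: str, seed: int):
    if kind == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if kind == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=100,
            random_state=seed,
        )
    raise ValueError(f"unknown comparator {kind!r}")


def _evaluate_loocv(
    X,
    y,
    config: NestedCVConfig,
    rankings: list[np.ndarray],
    classifier: str = "svm",
    resample_rng: np.random.Generator | None = None,
) -> list[FoldOutput]:
    n = X.shape[0]
    outputs = []
    for i in range(n):
        train = np.arange(n) != i
        X_tr, y_tr = X[train], y[train]
        if resample_rng is not None and config.resample != "none":
            X_tr, y_tr = _resample_training(X_tr, y_tr, config.resample, resample_rng)
        mu, sd = _train_scaler(X_tr)
        feats = rankings[i][: config.top_k]
        Z_tr = ((X_tr - mu) / sd)[:, feats]
        Z_te = ((X[i : i + 1] - mu) / sd)[:, feats]
        if classifier == "svm":
            model = GridSearchRBFSVM(
                C_grid=config.C_grid,
                sigma_grid=config.sigma_grid,
                inner_folds=config.inner_folds,
                random_state=config.seed + i,
            )
            model.fit(Z_tr, y_tr)
            pred = int(model.predict(Z_te)[0])
            score = float(model.decision_function(Z_te)[0])
            chosen_c, chosen_sigma = model.C_, model.sigma_
        else:
            model = clone(_make_comparator(classifier, config.seed + i))
            model.fit(Z_tr, y_tr)
            pred = int(model.predict(Z_te)[0])
            proba = model.predict_proba(Z_te)[0]
            score = float(proba[list(model.classes_).index(1)] - 0.5) if 1 in model.classes_ else -0.5
            chosen_c = chosen_sigma = None
        outputs.append(
            FoldOutput(
                held_out_index=i,
                true_label=int(y[i]),
                predicted_label=pred,
                decision_score=score,
                C=chosen_c,
                sigma=chosen_sigma,
                selected_features=tuple(int(f) for f in feats),
            )
        )
    return outputs


def nested_cv(X, y, config: NestedCVConfig) -> list[FoldOutput]:
    """Leave-one-out outer loop with per-fold selection and inner grid search."""
    X, y = _check_Xy(X, y)
    config.validate()
    rankings = fold_rankings(X, y, config)
    return _evaluate_loocv(X, y, config, rankings)


def comparator_fit(X, y, kind: str, config: NestedCVConfig) -> list[FoldOutput]:
    """Same outer protocol with a fixed comparator classifier (rf/knn/adaboost)."""
    X, y = _check_Xy(X, y)
    config.validate()
    rankings = fold_rankings(X, y, config)
    return _evaluate_loocv(X, y, config, rankings, classifier=kind)


def report_from_folds(folds: Sequence[FoldOutput]) -> ClassificationReport:
    """Aggregate out-of-fold predictions into a full report (positive = 1)."""
    y_true = np.array([f.true_label for f in folds])
    y_pred = np.array([f.predicted_label for f in folds])
    scores = np.array([f.decision_score for f in folds])
    return full_report(y_true, y_pred, scores, positive=1)


def resample_evaluate(
    X, y, config: NestedCVConfig, classifier: str = "svm"
) -> tuple[dict, list[ClassificationReport]]:
    """Average the LOOCV metrics over resampling iterations.

    Each iteration redraws the balanced training sets (the held-out side is
    never resampled), reruns the leave-one-out evaluation, and the metric
    means across iterations are reported.
    """
    X, y = _check_Xy(X, y)
    config.validate()
    if config.resample == "none":
        raise ValueError("resample_evaluate requires a resampling mode")
    rankings = fold_rankings(X, y, config)
    reports = []
    for it in range(config.resample_iterations):
        rng = np.random.default_rng((config.seed, it))
        folds = _evaluate_loocv(X, y, config, rankings, classifier=classifier, resample_rng=rng)
        reports.append(report_from_folds(folds))
    mean = {
        metric: float(np.mean([getattr(r, metric) for r in reports]))
        for metric in ("acc", "sen", "spe", "bac", "auc")
        if all(getattr(r, metric) is not None for r in reports)
    }
    return mean, reports
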