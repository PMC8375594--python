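"""Feature-selection algorithms behind one sklearn-style interface.

Three selectors, all ``SelectorMixin`` transformers usable inside sklearn
pipelines:

``RSFSSelector``
    Random subset feature selection.  Each iteration draws a random feature
    subset, scores it with a KNN criterion on an internal stratified split,
    and credits every used feature with the criterion's excess over its
    running mean, ``r' = r + c_i - E{c}``.  A parallel pool of dummy
    features receives the same updates from random draws; a feature is kept
    when the Gaussian fit to the dummy relevances puts its relevance above
    the ``delta`` quantile.

``MRMRSelector``
    Greedy minimal-redundancy-maximal-relevance ranking: each step adds the
    feature maximizing mean mutual information with the class minus the
    mean pairwise mutual information within the candidate set (features
    discretized into three bins at mean +/- SD, plug-in MI in bits).

``L1StabilitySelector``
    Stability selection over L1-penalized linear regression: on each of B
    stratified half-subsamples and every penalty on the lambda grid, fit
    the lasso on +/-1-coded labels; a feature's stability score is the
    maximum over lambda of the fraction of subsamples in which its
    coefficient is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import lasso_path
from sklearn.utils.validation import check_is_fitted, check_X_y

#: printed lasso penalty grid: 0.05 < lambda < 0.3, step 0.005.
LAMBDA_GRID: np.ndarray = np.round(np.arange(0.055, 0.2999, 0.005), 3)


@dataclass
class SelectionResult:
    """Ranked output of one selector fit."""

    algorithm: str
    scores: np.ndarray          # per-feature score, higher = better
    ranking: np.ndarray         # 0-based feature columns, best first
    selected: np.ndarray        # 0-based columns passing the selection rule
    params: dict

    def top(self, k: int) -> np.ndarray:
        return self.ranking[:k]


@lru_cache(maxsize=8)
def _z_quantile(delta: float) -> float:
    return float(norm.ppf(delta))


def _rank_desc(scores: np.ndarray, tiebreak: np.ndarray | None = None) -> np.ndarray:
    """Descending-score ranking; ties by ``tiebreak`` then ascending index."""
    p = scores.size
    if tiebreak is None:
        tiebreak = np.zeros(p)
    return np.lexsort((np.arange(p), -tiebreak, -scores))


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# RSFS


def _knn_balanced_accuracy(
    X_train: np.ndarray, y_train: np.ndarray, X_val: np.ndarray, y_val: np.ndarray, k: int
) -> float:
    """Balanced accuracy of a k-NN majority vote (Euclidean distance)."""
    d = cdist(X_val, X_train)
    k = min(k, X_train.shape[0])
    nn = np.argpartition(d, k - 1, axis=1)[:, :k]
    votes = y_train[nn].mean(axis=1)
    pred = (votes > 0.5).astype(int)
    accs = [np.mean(pred[y_val == c] == c) for c in (0, 1) if np.any(y_val == c)]
    return float(np.mean(accs))


class RSFSSelector(SelectorMixin, BaseEstimator):
    """Random subset feature selection with a dummy-feature null.

    Parameters
    ----------
    n_subset : int, optional
        Features drawn per iteration; defaults to ``ceil(sqrt(p))``.
    n_dummy_pool : int, optional
        Number of dummy columns the null Gaussian is fitted to; defaults
        to ``max(p, 200)`` -- at least 200 so the fitted null's tail
        quantile is stable.  In ``"shared"`` mode the pool is *not* a free
        knob: dummies must be drawn at the same rate as true features
        (``n_subset`` of ``p``) for their relevance variance to match the
        true-feature null, so the pool is forced to ``p`` there.
    delta : float
        Selection threshold on ``P(r_j > r_rand)`` under the dummy Gaussian.
    n_iter : int, optional
        Iteration budget.  The default (``None``) targets 50 expected
        inclusions per feature, ``ceil(50 * p / n_subset)`` -- enough draws
        for the relevance ranking to stabilize at any feature count, while
        keeping the dummy null roughly calibrated: with much longer
        budgets the relevance of features merely *chance-correlated* with
        the labels grows linearly in their inclusion count while the dummy
        null grows only as its square root, inflating the false-selection
        rate (see the methods note).
    patience : int
        Early-stop window: iteration stops once the selected set is
        unchanged for ``patience`` consecutive iterations.
    knn_k, val_fraction, n_splits : KNN criterion settings.  Each
        iteration's criterion is the balanced accuracy averaged over
        ``n_splits`` fresh stratified 75/25 splits; on cohorts of under a
        hundred subjects a single split is quantized to steps of a few
        percent, and averaging a handful of splits markedly sharpens the
        relevance ranking at modest cost.
    dummy_mode : {"pooled", "shared"}
        How the dummy null is fed.  ``"pooled"`` (default) appends
        label-decoupled dummy columns (each true column row-permuted once
        at fit time) to the candidate pool, so dummies compete inside the
        very same subset draws and KNN evaluations as true features; a
        dummy relevance is then exchangeable with that of an irrelevant
        true feature -- it carries the identical in-sample
        chance-correlation variance and the identical "spillover" variance
        from co-occurring with informative features -- and the Gaussian
        null stays calibrated at any iteration budget.  ``"shared"``
        updates a separate dummy pool with the true subset's criterion
        value; this bookkeeping null cannot see chance correlation and
        becomes anti-conservative on small cohorts as the budget grows.
    criterion : callable, optional
        ``f(X, y01, subset, rng) -> float`` replacing the KNN balanced
        accuracy (used for testing the relevance-update rule).
    """

    def __init__(
        self,
        n_subset: int | None = None,
        n_dummy_pool: int | None = None,
        delta: float = 0.99,
        n_iter: int | None = None,
        patience: int = 500,
        knn_k: int = 5,
        val_fraction: float = 0.25,
        n_splits: int = 3,
        dummy_mode: str = "pooled",
        criterion: Callable | None = None,
        random_state: int | None = None,
    ):
        self.n_subset = n_subset
        self.n_dummy_pool = n_dummy_pool
        self.delta = delta
        self.n_iter = n_iter
        self.patience = patience
        self.knn_k = knn_k
        self.val_fraction = val_fraction
        self.n_splits = n_splits
        self.dummy_mode = dummy_mode
        self.criterion = criterion
        self.random_state = random_state

    def _stratified_split(self, rng, y):
        train_idx, val_idx = [], []
        for c in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == c))
            n_val = max(1, int(round(self.val_fraction * idx.size)))
            n_val = min(n_val, idx.size - 1)
            val_idx.append(idx[:n_val])
            train_idx.append(idx[n_val:])
        return np.concatenate(train_idx), np.concatenate(val_idx)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("RSFS requires at least 2 classes")
        if X.shape[0] < 8:
            raise ValueError("RSFS requires at least 8 subjects")
        y01 = np.searchsorted(classes, y)
        if classes.size > 2:
            raise ValueError("RSFS is a two-class selector")
        if self.dummy_mode not in ("pooled", "shared"):
            raise ValueError(f"unknown dummy_mode {self.dummy_mode!r}")
        rng = np.random.default_rng(self.random_state)
        p = X.shape[1]
        n_sub = min(self.n_subset or int(np.ceil(np.sqrt(p))), p)
        if self.dummy_mode == "shared":
            n_pool = p  # inclusion rates must match the true features
        else:
            n_pool = self.n_dummy_pool or max(p, 200)
        Xz = _zscore_columns(X)

        def default_criterion(mat, _y, subset, r):
            # one all-subjects distance matrix on the subset, shared by splits
            sub = mat[:, subset]
            sq = np.einsum("ij,ij->i", sub, sub)
            dist = sq[:, None] + sq[None, :] - 2.0 * (sub @ sub.T)
            vals = []
            for _ in range(self.n_splits):
                tr, va = self._stratified_split(r, y01)
                block = dist[np.ix_(va, tr)]
                k = min(self.knn_k, tr.size)
                nn = np.argpartition(block, k - 1, axis=1)[:, :k]
                pred = (y01[tr][nn].mean(axis=1) > 0.5).astype(int)
                accs = [
                    float(np.mean(pred[y01[va] == c] == c))
                    for c in (0, 1)
                    if np.any(y01[va] == c)
                ]
                vals.append(float(np.mean(accs)))
            return float(np.mean(vals))

        criterion = self.criterion or default_criterion
        true_mat = Xz if self.criterion is None else X
        pooled = self.dummy_mode == "pooled"
        if pooled:
            # label-decoupled dummy columns: each true column row-permuted once
            cols = np.arange(p) if n_pool == p else rng.integers(0, p, size=n_pool)
            dummy_mat = np.column_stack([rng.permutation(true_mat[:, c]) for c in cols])
            draw_mat = np.hstack([true_mat, dummy_mat])
            n_draw = p + n_pool
        else:
            draw_mat = true_mat
            n_draw = p
        # default budget: ~50 expected inclusions per candidate column
        n_iter = self.n_iter or int(np.ceil(50 * n_draw / n_sub))

        relevance = np.zeros(n_draw)
        dummy = np.zeros(n_pool)  # shared mode only; pooled reads relevance[p:]
        crit_sum = 0.0
        selected_mask = np.zeros(p, dtype=bool)
        unchanged = 0
        history = []
        for it in range(1, n_iter + 1):
            subset = rng.choice(n_draw, size=n_sub, replace=False)
            c_i = float(criterion(draw_mat, y01, subset, rng))
            crit_sum += c_i
            history.append(c_i)
            step = c_i - crit_sum / it
            relevance[subset] += step
            if not pooled:
                dummy_subset = rng.choice(n_pool, size=min(n_sub, n_pool), replace=False)
                dummy[dummy_subset] += step

            null = relevance[p:] if pooled else dummy
            # threshold form of the Gaussian selection rule (fast path)
            sigma = null.std(ddof=1) if null.size > 1 else 0.0
            if sigma == 0:
                mask = np.zeros(p, dtype=bool) if self.delta > 0.5 else np.ones(p, dtype=bool)
            else:
                mask = relevance[:p] > null.mean() + _z_quantile(self.delta) * sigma
            if np.array_equal(mask, selected_mask):
                unchanged += 1
            else:
                unchanged = 0
                selected_mask = mask
            if unchanged >= self.patience:
                break

        null = relevance[p:] if pooled else dummy
        self.n_iter_ = it
        self.relevances_ = relevance[:p]
        self.dummy_relevances_ = null
        self.criterion_history_ = np.asarray(history)
        self.mu_dummy_ = float(null.mean())
        self.sigma_dummy_ = float(null.std(ddof=1)) if null.size > 1 else 0.0
        self.scores_ = self._selection_probability(relevance[:p], null)
        self.support_ = self._selection_mask(relevance[:p], null)
        self.ranking_ = _rank_desc(self.scores_, tiebreak=relevance[:p])
        self.n_features_in_ = p
        return self

    def _selection_probability(self, relevance, dummy):
        mu = dummy.mean()
        sigma = dummy.std(ddof=1) if dummy.size > 1 else 0.0
        if sigma == 0:
            return np.full(relevance.size, 0.5)
        return norm.cdf((relevance - mu) / sigma)

    def _selection_mask(self, relevance, dummy):
        return self._selection_probability(relevance, dummy) >= self.delta

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def to_result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            algorithm="rsfs",
            scores=self.scores_,
            ranking=self.ranking_,
            selected=np.flatnonzero(self.support_),
            params={
                "delta": self.delta,
                "n_iter": self.n_iter_,
                "seed": self.random_state,
            },
        )


# ---------------------------------------------------------------------------
# mRMR


def discretize_three_bins(X: np.ndarray) -> np.ndarray:
    """Per-feature three-level coding with cut points at mean +/- SD."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X > mu - sd).astype(np.int8) + (X > mu + sd).astype(np.int8)


def mutual_information_bits(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy minimal-redundancy-maximal-relevance ranking.

    Each step adds the candidate maximizing the set criterion
    ``D(S) - R(S)`` on ``S = selected + candidate``, with ``D`` the mean
    feature-class MI and ``R`` the mean pairwise inter-feature MI (ordered
    distinct pairs, ``1/|S|^2`` normalization, self-information excluded so
    that the first pick is exactly the maximum-MI feature).
    """

    def __init__(self, k: int = 30, discretize: bool = True):
        self.k = k
        self.discretize = discretize

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds feature count {X.shape[1]}")
        Xd = discretize_three_bins(X) if self.discretize else X.astype(np.int64)
        p = Xd.shape[1]
        relevance = np.array([mutual_information_bits(Xd[:, j], y) for j in range(p)])

        ranking: list[int] = []
        objective: list[float] = []
        in_set = np.zeros(p, dtype=bool)
        pair_sum = np.zeros(p)  # sum over selected s of I(x_j; x_s)
        rel_sum = 0.0
        sel_pair_total = 0.0  # sum of I over unordered pairs within selected
        for _step in range(self.k):
            size = len(ranking) + 1
            d_term = (rel_sum + relevance) / size
            r_term = 2.0 * (sel_pair_total + pair_sum) / size**2
            scores = np.where(in_set, -np.inf, d_term - r_term)
            j = int(np.argmax(scores))  # ties: lowest index wins
            ranking.append(j)
            objective.append(float(scores[j]))
            in_set[j] = True
            rel_sum += relevance[j]
            sel_pair_total += pair_sum[j]
            new_mi = np.array(
                [0.0 if in_set[m] else mutual_information_bits(Xd[:, j], Xd[:, m]) for m in range(p)]
            )
            pair_sum += new_mi

        self.relevance_ = relevance
        self.ranking_ = np.asarray(ranking)
        self.objective_path_ = np.asarray(objective)
        # rank-based scores: earlier picks score higher
        scores = np.full(p, -np.inf)
        scores[self.ranking_] = np.arange(len(ranking), 0, -1, dtype=float)
        self.scores_ = scores
        self.support_ = in_set
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def to_result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            algorithm="mrmr",
            scores=self.scores_,
            ranking=self.ranking_,
            selected=self.ranking_.copy(),
            params={"k": self.k},
        )


# ---------------------------------------------------------------------------
# SS-LR


class L1StabilitySelector(SelectorMixin, BaseEstimator):
    """Stability selection over L1-penalized linear regression.

    The lasso objective is ``(1/n) ||X w - y||^2 + lambda ||w||_1`` (labels
    coded +/-1, columns z-scored per subsample, no intercept); a feature is
    selected when its stability score -- the maximum over the lambda grid
    of the fraction of subsamples with a nonzero coefficient -- reaches
    ``pi_threshold``.
    """

    def __init__(
        self,
        lambda_grid: Sequence[float] | None = None,
        n_subsamples: int = 100,
        pi_threshold: float = 0.6,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.lambda_grid = lambda_grid
        self.n_subsamples = n_subsamples
        self.pi_threshold = pi_threshold
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n, p = X.shape
        if n < 8:
            raise ValueError("stability selection requires at least 8 subjects")
        grid = np.asarray(self.lambda_grid if self.lambda_grid is not None else LAMBDA_GRID)
        if grid.size == 0:
            raise ValueError("lambda grid must be nonempty")
        classes = np.unique(y)
        is_classification = classes.size == 2
        yv = np.where(y == classes[1], 1.0, -1.0) if is_classification else y.astype(float)

        rng = np.random.default_rng(self.random_state)
        half = n // 2
        freq = np.zeros((grid.size, p))
        # lasso_path expects descending alphas; our loss has alpha = lambda/2
        order = np.argsort(grid)[::-1]
        alphas_desc = grid[order] / 2.0
        for _b in range(self.n_subsamples):
            idx = self._subsample(rng, yv if is_classification else None, n, half)
            Xs = _zscore_columns(X[idx])
            ys = yv[idx]
            _, coefs, _ = lasso_path(Xs, ys, alphas=alphas_desc, tol=self.tol)
            nonzero = np.abs(coefs.T) > 1e-8  # (n_alphas, p)
            freq[order] += nonzero
        freq /= self.n_subsamples

        self.lambda_grid_ = grid
        self.selection_frequency_ = freq
        self.scores_ = freq.max(axis=0)
        self.support_ = self.scores_ >= self.pi_threshold
        self.ranking_ = _rank_desc(self.scores_)
        self.n_features_in_ = p
        return self

    @staticmethod
    def _subsample(rng, y_signed, n, half):
        if y_signed is None:
            return rng.choice(n, size=half, replace=False)
        idx = []
        for sign in (-1.0, 1.0):
            members = np.flatnonzero(y_signed == sign)
            take = max(1, int(round(half * members.size / n)))
            idx.append(rng.choice(members, size=min(take, members.size), replace=False))
        return np.concatenate(idx)

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def to_result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            algorithm="sslr",
            scores=self.scores_,
            ranking=self.ranking_,
            selected=np.flatnonzero(self.support_),
            params={
                "n_subsamples": self.n_subsamples,
                "pi_threshold": self.pi_threshold,
                "seed": self.random_state,
            },
        )


# ---------------------------------------------------------------------------


def make_selector(name: str, seed: int | None = None, **params):
    """Factory for the three selectors by short name."""
    if name == "rsfs":
        return RSFSSelector(random_state=seed, **params)
    if name == "mrmr":
        return MRMRSelector(**params)
    if name == "sslr":
        return L1StabilitySelector(random_state=seed, **params)
    raise ValueError(f"unknown selector {name!r}")


def selection_frequency(
    per_fold: Sequence, n_features: int | None = None
) -> pd.DataFrame:
    """Cross-fold selection frequency table.

    ``per_fold`` holds, per fold, either a :class:`SelectionResult` or a
    collection of selected feature indices.  Frequency is the percentage of
    folds selecting the feature, sorted descending with ties broken by
    ascending index.
    """
    if len(per_fold) == 0:
        raise ValueError("need at least one fold")
    fold_sets = [
        np.asarray(f.selected if isinstance(f, SelectionResult) else list(f), dtype=int)
        for f in per_fold
    ]
    if n_features is None:
        universe = np.unique(np.concatenate([s for s in fold_sets if s.size] or [np.array([], int)]))
    else:
        universe = np.arange(n_features)
    counts = np.zeros(universe.size)
    lookup = {int(f): i for i, f in enumerate(universe)}
    for s in fold_sets:
        for f in np.unique(s):
            counts[lookup[int(f)]] += 1
    freq = 100.0 * counts / len(fold_sets)
    table = pd.DataFrame({"feature": universe, "frequency": freq})
    return table.sort_values(
        ["frequency", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
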