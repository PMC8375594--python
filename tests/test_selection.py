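"""The three feature-selection algorithms and the frequency aggregation."""

import numpy as np
import pytest

from mcinet import L1StabilitySelector, MRMRSelector, RSFSSelector, selection_frequency
from mcinet.selection import (
    LAMBDA_GRID,
    SelectionResult,
    discretize_three_bins,
    make_selector,
    mutual_information_bits,
)

from .oracles import oracle_mi_bits, oracle_mrmr_ranking


def planted_data(seed, n=60, p=100, n_signal=5, effect=1.5):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[:, :n_signal] += effect * y[:, None]
    return X, y


class TestRSFS:
    def test_relevance_update_rule(self):
        """r' = r + c_i - E{c}: two iterations with a scripted criterion."""
        sequence = iter([0.6, 0.8])

        def scripted(_X, _y, _subset, _rng):
            return next(sequence)

        X = np.random.default_rng(0).standard_normal((20, 4))
        y = np.repeat([0, 1], 10)
        sel = RSFSSelector(
            n_subset=4, n_iter=2, dummy_mode="shared", criterion=scripted, random_state=0
        ).fit(X, y)
        # step1 = 0.6 - 0.6 = 0; step2 = 0.8 - 0.7 = 0.1; every feature used
        np.testing.assert_allclose(sel.relevances_, 0.1)
        np.testing.assert_allclose(sel.criterion_history_, [0.6, 0.8])

    def test_constant_criterion_selects_nothing(self):
        """Zero spread: every p(r_j < r_rand) falls back to 0.5 < delta."""
        X = np.random.default_rng(0).standard_normal((20, 6))
        y = np.repeat([0, 1], 10)
        # 0.75 is exact in binary, so every step is exactly zero
        sel = RSFSSelector(
            n_iter=50, dummy_mode="shared", criterion=lambda *a: 0.75, random_state=0
        ).fit(X, y)
        np.testing.assert_allclose(sel.scores_, 0.5)
        assert sel.support_.sum() == 0

    def test_planted_features_rank_first(self):
        X, y = planted_data(seed=0)
        sel = RSFSSelector(random_state=0).fit(X, y)
        assert set(sel.ranking_[:5]) == {0, 1, 2, 3, 4}
        chosen = np.flatnonzero(sel.support_)
        assert np.sum(chosen < 5) >= 4

    def test_null_calibration(self):
        """On pure noise the dummy null keeps false selections near nominal."""
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((200, 100))
            y = np.repeat([0, 1], 100)
            sel = RSFSSelector(delta=0.99, random_state=seed).fit(X, y)
            counts.append(sel.support_.sum())
        assert np.mean(counts) <= 2.0  # <= 2% of 100 features

    def test_deterministic_under_seed(self):
        X, y = planted_data(seed=3)
        a = RSFSSelector(n_iter=120, random_state=7).fit(X, y)
        b = RSFSSelector(n_iter=120, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.ranking_, b.ranking_)
        np.testing.assert_allclose(a.relevances_, b.relevances_)

    def test_rejects_degenerate_inputs(self):
        X = np.zeros((20, 5))
        with pytest.raises(ValueError):
            RSFSSelector().fit(X, np.zeros(20))  # one class
        with pytest.raises(ValueError):
            RSFSSelector().fit(X[:6], np.repeat([0, 1], 3))  # too few subjects


class TestMRMR:
    def test_mi_matches_oracle(self, rng):
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 2, 200)
        assert mutual_information_bits(a, b) == pytest.approx(oracle_mi_bits(a, b))

    def test_three_bin_discretization(self):
        x = np.array([[-5.0], [0.0], [5.0], [0.1], [-0.1], [0.0]])
        d = discretize_three_bins(x)
        assert d.min() == 0 and d.max() == 2

    def test_label_copy_is_first_pick(self, rng):
        y = rng.integers(0, 2, 80)
        X = rng.standard_normal((80, 6))
        X[:, 3] = y * 10.0
        sel = MRMRSelector(k=3).fit(X, y)
        assert sel.ranking_[0] == 3

    def test_duplicate_loses_to_independent_noise(self):
        """A copy of an informative feature is pure redundancy; noise is not."""
        rng = np.random.default_rng(5)
        n = 60
        y = np.repeat([0, 1], n // 2)
        f1 = y.astype(float).copy()
        flips = rng.choice(n, 6, replace=False)
        f1[flips] = 1 - f1[flips]
        X = np.column_stack([f1 * 4, f1 * 4, rng.standard_normal(n)])
        sel = MRMRSelector(k=3).fit(X, y)
        assert sel.ranking_[0] in (0, 1)
        assert sel.ranking_[1] == 2  # noise beats the exact duplicate

    def test_matches_exhaustive_greedy_oracle(self, rng):
        Xd = rng.integers(0, 3, size=(50, 8))
        y = (Xd[:, 0] + rng.integers(0, 2, 50) >= 2).astype(int)
        ours = MRMRSelector(k=8, discretize=False).fit(Xd, y).ranking_
        oracle = oracle_mrmr_ranking(Xd, y, k=8)
        np.testing.assert_array_equal(ours, oracle)

    def test_k_validation(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError):
            MRMRSelector(k=0).fit(X, y)
        with pytest.raises(ValueError):
            MRMRSelector(k=6).fit(X, y)


class TestStabilitySelection:
    def test_printed_lambda_grid(self):
        assert LAMBDA_GRID[0] == pytest.approx(0.055)
        assert LAMBDA_GRID[-1] == pytest.approx(0.295)
        assert len(LAMBDA_GRID) == 49
        np.testing.assert_allclose(np.diff(LAMBDA_GRID), 0.005)

    def test_penalty_above_lambda_max_selects_nothing(self, rng):
        X = rng.standard_normal((60, 10))
        y = np.repeat([0, 1], 30)
        # columns are z-scored per subsample and |y| = 1, so lambda_max =
        # (2/n)|X^T y| <= 2 < 4 always: the all-zero solution everywhere
        sel = L1StabilitySelector(lambda_grid=[4.0], n_subsamples=20, random_state=0).fit(X, y)
        assert sel.support_.sum() == 0
        assert sel.scores_.max() == 0.0

    def test_single_signal_support_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 20))
        y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(100)
        sel = L1StabilitySelector(n_subsamples=100, random_state=0).fit(X, y)
        assert sel.scores_[0] >= 0.9
        np.testing.assert_array_equal(np.flatnonzero(sel.support_), [0])

    def test_score_monotone_in_effect_size(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 10))
        noise = rng.standard_normal(100)
        scores = []
        for beta in (0.05, 0.2, 1.0):
            y = beta * X[:, 0] + 0.5 * noise
            sel = L1StabilitySelector(n_subsamples=50, random_state=2).fit(X, y)
            scores.append(sel.scores_[0])
        assert scores[0] <= scores[1] <= scores[2]

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((40, 12))
        y = np.repeat([0, 1], 20)
        a = L1StabilitySelector(n_subsamples=30, random_state=4).fit(X, y)
        b = L1StabilitySelector(n_subsamples=30, random_state=4).fit(X, y)
        np.testing.assert_allclose(a.scores_, b.scores_)

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            L1StabilitySelector().fit(rng.standard_normal((6, 4)), np.repeat([0, 1], 3))


class TestSelectorInterface:
    def test_factory_and_results(self):
        X, y = planted_data(seed=2, n=40, p=30)
        for name in ("rsfs", "mrmr", "sslr"):
            sel = make_selector(name, seed=0, **({"k": 10} if name == "mrmr" else {}))
            sel.fit(X, y)
            result = sel.to_result()
            assert result.algorithm == name
            assert len(result.ranking) >= 10
            assert set(result.selected) <= set(range(30))
            # transform respects the support mask
            assert sel.transform(X).shape == (40, int(sel.get_support().sum()))
        with pytest.raises(ValueError):
            make_selector("pca")

    def test_column_permutation_equivariance(self):
        """Permuting feature columns relabels the ranking identically."""
        X, y = planted_data(seed=4, n=50, p=20, n_signal=3)
        perm = np.random.default_rng(0).permutation(20)
        base = MRMRSelector(k=20).fit(X, y).ranking_
        shuffled = MRMRSelector(k=20).fit(X[:, perm], y).ranking_
        np.testing.assert_array_equal(perm[shuffled], base)


class TestSelectionFrequency:
    def test_percentages_match_fold_counts(self):
        folds = [{1, 2}] * 31 + [{2}] * 54
        table = selection_frequency(folds)
        freq = dict(zip(table["feature"], table["frequency"]))
        assert freq[2] == pytest.approx(100.0)
        assert freq[1] == pytest.approx(100.0 * 31 / 85)
        assert round(freq[1], 2) == 36.47

    def test_sorting_and_zero_entries(self):
        folds = [SelectionResult("rsfs", np.zeros(5), np.arange(5), np.array([3]), {})] * 4
        table = selection_frequency(folds, n_features=5)
        assert list(table["feature"][:1]) == [3]
        assert table["frequency"].iloc[0] == 100.0
        assert set(table["frequency"][1:]) == {0.0}
        # ties broken by ascending feature index
        assert list(table["feature"][1:]) == [0, 1, 2, 4]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            selection_frequency([])
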