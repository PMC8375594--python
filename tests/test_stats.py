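"""Evaluation statistics: confusion metrics, exact CIs, AUC, McNemar."""

import numpy as np
import pytest

from mcinet import (
    clopper_pearson,
    confusion_metrics,
    delong_ci,
    delong_paired_test,
    full_report,
    mcnemar_test,
    roc_auc,
)
from mcinet.stats import delong_variance


def _predictions(tp, fn, tn, fp):
    y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
    y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
    return y_true, y_pred


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, acc, sen, spe, bac",
        [
            ((20, 10, 52, 3), 84.71, 66.67, 94.55, 80.61),
            ((15, 4, 29, 1), 89.80, 78.95, 96.67, 87.81),
        ],
    )
    def test_worked_examples(self, counts, acc, sen, spe, bac):
        """Confusion counts of the two study contrasts reproduce ACC/SEN/SPE/BAC."""
        y_true, y_pred = _predictions(*counts)
        rep = confusion_metrics(y_true, y_pred, positive=1)
        assert round(100 * rep.acc, 2) == acc
        assert round(100 * rep.sen, 2) == sen
        assert round(100 * rep.spe, 2) == spe
        assert round(100 * rep.bac, 2) == bac

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = confusion_metrics(y, y, positive=1)
        assert rep.acc == rep.sen == rep.spe == rep.bac == 1.0

    def test_single_class_rates_are_missing_not_zero(self):
        y_true = np.zeros(6, dtype=int)
        y_pred = np.array([0, 0, 1, 0, 0, 0])
        rep = confusion_metrics(y_true, y_pred, positive=1)
        assert rep.sen is None and rep.bac is None
        assert rep.spe == pytest.approx(5 / 6)

    def test_bac_identity(self, rng):
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        rep = confusion_metrics(y_true, y_pred, positive=1)
        if rep.bac is not None:
            assert rep.bac == pytest.approx((rep.sen + rep.spe) / 2)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k, n, lo, hi",
        [
            (72, 85, 75.27, 91.60),
            (20, 30, 47.19, 82.71),
            (52, 55, 84.88, 98.86),
            (44, 49, 77.77, 96.60),
            (15, 19, 54.43, 93.95),
            (29, 30, 82.78, 99.92),
        ],
    )
    def test_published_interval_bounds(self, k, n, lo, hi):
        got = clopper_pearson(k, n, 0.95)
        assert round(100 * got[0], 2) == lo
        assert round(100 * got[1], 2) == hi

    def test_boundary_cases(self):
        assert clopper_pearson(0, 12)[0] == 0.0
        assert clopper_pearson(12, 12)[1] == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)
        with pytest.raises(ValueError):
            clopper_pearson(1, 10, level=1.5)

    def test_simulated_coverage(self):
        """Exact interval covers the true p at >= 94% across p and n."""
        rng = np.random.default_rng(0)
        for p_true in (0.1, 0.5, 0.9):
            for n in (20, 50, 100):
                k = rng.binomial(n, p_true, size=2000)
                # vectorized exact bounds via the beta quantiles
                from scipy.stats import beta

                lo = np.where(k > 0, beta.ppf(0.025, k, n - k + 1), 0.0)
                hi = np.where(k < n, beta.ppf(0.975, k + 1, n - k), 1.0)
                coverage = np.mean((lo <= p_true) & (p_true <= hi))
                assert coverage >= 0.94


class TestROCAndDeLong:
    def test_hand_enumerated_auc(self):
        scores = np.array([0.9, 0.8, 0.85, 0.7])
        labels = np.array([1, 1, 0, 0])
        _, auc = roc_auc(scores, labels, positive=1)
        assert auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_degenerate_aucs(self):
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(np.array([5, 4, 3, 2]), labels, 1)[1] == 1.0
        assert roc_auc(np.ones(4), labels, 1)[1] == 0.5
        with pytest.raises(ValueError):
            roc_auc(np.ones(3), np.ones(3), 1)

    def test_roc_polyline_properties(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        roc, auc = roc_auc(scores, labels, positive=1)
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)
        assert auc == pytest.approx(np.trapezoid(roc[:, 1], roc[:, 0]))

    def test_ci_contains_point_estimate(self, rng):
        scores = rng.standard_normal(60)
        labels = (rng.random(60) < 0.4).astype(int)
        scores[labels == 1] += 1.0
        _, auc = roc_auc(scores, labels, 1)
        lo, hi = delong_ci(scores, labels, 1)
        assert lo <= auc <= hi

    def test_interval_shrinks_with_sample_size(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (20, 80, 320):
            w = []
            for _ in range(40):
                labels = np.repeat([0, 1], n // 2)
                scores = rng.standard_normal(n) + labels
                lo, hi = delong_ci(scores, labels, 1)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]
        # asymptotically ~ 1/sqrt(n): a 16x larger sample shrinks ~4x
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.35)

    def test_variance_agrees_with_bootstrap(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 50)
        scores = rng.standard_normal(100) + 0.8 * labels
        _, var = delong_variance(scores, labels, 1)
        boots = []
        for _ in range(600):
            idx = np.concatenate(
                [rng.choice(50, 50, replace=True), 50 + rng.choice(50, 50, replace=True)]
            )
            from sklearn.metrics import roc_auc_score

            boots.append(roc_auc_score(labels[idx], scores[idx]))
        assert var == pytest.approx(np.var(boots), rel=0.25)

    def test_perfect_separation_collapses_interval(self):
        labels = np.repeat([0, 1], 5)
        scores = np.arange(10, dtype=float)
        lo, hi = delong_ci(scores, labels, 1)
        assert lo == hi == 1.0

    def test_paired_test_symmetry_and_null(self, rng):
        labels = np.repeat([0, 1], 30)
        a = rng.standard_normal(60) + labels
        b = a + 0.01 * rng.standard_normal(60)
        diff, p = delong_paired_test(a, b, labels, 1)
        assert p > 0.05
        diff_rev, p_rev = delong_paired_test(b, a, labels, 1)
        assert diff_rev == pytest.approx(-diff)
        assert p_rev == pytest.approx(p)


class TestMcNemar:
    def test_symmetric_discordance(self):
        y = np.zeros(20, dtype=int)
        a = y.copy()
        a[:5] = 1  # A wrong on 5
        b = y.copy()
        b[5:10] = 1  # B wrong on a disjoint 5
        assert mcnemar_test(a, b, y) == pytest.approx(1.0)

    def test_one_sided_discordance(self):
        y = np.zeros(30, dtype=int)
        a = y.copy()  # A always right
        b = y.copy()
        b[:10] = 1  # B wrong on 10
        assert mcnemar_test(a, b, y) == pytest.approx(2 * 0.5**10, rel=1e-6)

    def test_swap_invariance_and_no_discordance(self, rng):
        y = rng.integers(0, 2, 40)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        assert mcnemar_test(a, b, y) == pytest.approx(mcnemar_test(b, a, y))
        assert mcnemar_test(a, a, y) == 1.0

    def test_chi2_variant_close_to_exact_for_large_counts(self, rng):
        y = np.zeros(400, dtype=int)
        a = y.copy()
        a[:60] = 1
        b = y.copy()
        b[300:390] = 1
        exact = mcnemar_test(a, b, y, exact=True)
        chi2 = mcnemar_test(a, b, y, exact=False)
        assert chi2 == pytest.approx(exact, rel=0.25)


def test_full_report_assembles_everything(rng):
    labels = np.repeat([0, 1], 25)
    scores = rng.standard_normal(50) + 1.2 * labels
    preds = (scores > 0.5).astype(int)
    rep = full_report(labels, preds, scores, positive=1)
    assert rep.n == 50
    assert rep.ci_acc[0] <= rep.acc <= rep.ci_acc[1]
    assert rep.ci_sen[0] <= rep.sen <= rep.ci_sen[1]
    assert rep.ci_auc[0] <= rep.auc <= rep.ci_auc[1]
    assert rep.bac == pytest.approx((rep.sen + rep.spe) / 2)
    as_dict = rep.as_dict()
    assert as_dict["tp"] + as_dict["tn"] + as_dict["fp"] + as_dict["fn"] == 50
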