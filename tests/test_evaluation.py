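import numpy as np
import pytest
from sklearn.metrics import log_loss, matthews_corrcoef

from enhancerrl.evaluation import (ConfusionCounts, auc, confusion,
                                   counts_from_rates, evaluate, mcnemar,
                                   metrics)
from enhancerrl.training import bce_loss


class TestConfusion:
    def test_examples(self):
        c = confusion([0.9, 0.1], [1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)
        c = confusion(np.zeros(7), np.ones(7))
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 0, 7)

    def test_matches_per_sample_loop(self):
        rng = np.random.default_rng(3)
        probs = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        c = confusion(probs, labels)
        tp = tn = fp = fn = 0
        for p, y in zip(probs, labels):
            pred = 1 if p >= 0.5 else 0
            if pred and y:
                tp += 1
            elif pred and not y:
                fp += 1
            elif not pred and y:
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 1000

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_category_benchmark_row(self):
        # SN 0.90 / SP 0.92 on a balanced 200+200 test set
        report = metrics(ConfusionCounts(tp=180, tn=184, fp=16, fn=20))
        assert report.acc == pytest.approx(0.9100, abs=5e-5)
        assert report.sn == pytest.approx(0.9000, abs=5e-5)
        assert report.sp == pytest.approx(0.9200, abs=5e-5)
        assert report.mcc == pytest.approx(0.8202, abs=5e-5)

    def test_strength_benchmark_row(self):
        # SN 0.95 / SP 0.67 on a balanced 100+100 test set
        report = metrics(ConfusionCounts(tp=95, tn=67, fp=33, fn=5))
        assert report.acc == pytest.approx(0.8100, abs=5e-5)
        assert report.mcc == pytest.approx(0.6458, abs=5e-5)

    def test_degenerate_counts_mcc_zero(self):
        report = metrics(ConfusionCounts(tp=10, tn=0, fp=0, fn=0))
        assert report.acc == 1.0 and report.sn == 1.0
        assert report.mcc == 0.0

    def test_matches_sklearn_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(0, 40, 4)
            if tp + tn + fp + fn == 0:
                continue
            report = metrics(ConfusionCounts(tp, tn, fp, fn))
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            assert report.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-10)

    def test_balanced_accuracy_identity(self):
        """On balanced classes ACC == (SN + SP) / 2 exactly."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            tp = int(rng.integers(0, n + 1))
            tn = int(rng.integers(0, n + 1))
            report = metrics(ConfusionCounts(tp, tn, n - tn, n - tp))
            assert report.acc == pytest.approx((report.sn + report.sp) / 2)

    def test_counts_from_rates_inverts_metrics(self):
        c = counts_from_rates(0.90, 0.92, 200, 200)
        assert (c.tp, c.tn, c.fp, c.fn) == (180, 184, 16, 20)


class TestAuc:
    def test_perfect_and_reversed(self):
        labels = [0, 0, 1, 1]
        assert auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert auc([-0.1, -0.2, -0.8, -0.9], labels) == pytest.approx(
            1.0 - auc([0.1, 0.2, 0.8, 0.9], labels))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 4000
        value = auc(rng.random(n), rng.integers(0, 2, n))
        se = np.sqrt(1 / 12) / np.sqrt(n / 2)   # rough rank-statistic scale
        assert abs(value - 0.5) < 3 * se + 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        base = auc(scores, labels)
        assert auc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert auc(scores ** 3, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestMcNemar:
    def test_symmetric_discordance_gives_one(self):
        labels = np.array([1, 1, 0, 0])
        a = np.array([1, 0, 0, 1])   # right, wrong, right, wrong
        b = np.array([0, 1, 0, 1])   # wrong, right, right, wrong
        assert mcnemar(a, b, labels) == 1.0

    def test_identical_predictions_warn_and_return_one(self):
        preds = np.array([1, 0, 1])
        with pytest.warns(UserWarning, match="discordant"):
            assert mcnemar(preds, preds, np.array([1, 0, 0])) == 1.0

    def test_exact_binomial_tail(self):
        # b01=1, b10=9: two-sided exact p = 2 * (C(10,0)+C(10,1)) / 2^10
        labels = np.ones(10, dtype=int)
        a = np.zeros(10, dtype=int)
        a[0] = 1                      # a right once where b is wrong
        b = np.ones(10, dtype=int)
        b[0] = 0
        expected = 2 * (1 + 10) / 2 ** 10
        assert mcnemar(a, b, labels) == pytest.approx(expected, abs=1e-10)


class TestBce:
    def test_closed_forms(self):
        assert bce_loss([1 - 1e-7], [1.0]) == pytest.approx(0.0, abs=1e-6)
        assert bce_loss([0.5, 0.5], [1.0, 0.0]) == pytest.approx(np.log(2))

    def test_matches_hand_summed_oracle(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(0.01, 0.99, 64)
        labels = rng.integers(0, 2, 64).astype(float)
        by_hand = -np.mean([y * np.log(p) + (1 - y) * np.log(1 - p)
                            for p, y in zip(probs, labels)])
        assert bce_loss(probs, labels) == pytest.approx(by_hand, abs=1e-6)
        assert bce_loss(probs, labels) == pytest.approx(
            log_loss(labels, probs), abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([], [])


def test_evaluate_full_report():
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 2, 200)
    probs = np.clip(labels * 0.7 + rng.normal(0, 0.2, 200) + 0.15, 0.001, 0.999)
    report = evaluate(probs, labels)
    assert 0 <= report.acc <= 1 and -1 <= report.mcc <= 1
    assert report.auc is not None and 0.5 < report.auc <= 1
    row = report.as_row()
    assert len(row.split("\t")) == 5
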