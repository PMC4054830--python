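"""Chou-form metrics, their equivalence with the textbook formulas, and the
jackknife protocol."""

import math

import numpy as np
import pytest

from methylsite.encoder import N_FEATURES
from methylsite.metrics import (
    ChouCounts,
    ConfusionCounts,
    JackknifeReport,
    MetricSet,
    MetricsError,
    average_reports,
    chou_metrics,
    chou_to_confusion,
    confusion_to_chou,
    counts_from_predictions,
    jackknife_evaluate,
    loo_predictions,
    run_balanced_jackknife,
    write_report_tsv,
)


def textbook_metrics(tp, tn, fp, fn):
    """Independent oracle: the TP/TN/FP/FN formulas, implemented directly."""
    sn = tp / (tp + fn) if tp + fn else None
    sp = tn / (tn + fp) if tn + fp else None
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, acc, mcc


class TestCountConversions:
    def test_worked_example_counts(self):
        chou = confusion_to_chou(ConfusionCounts(tp=1, tn=12, fp=1, fn=0))
        assert chou == ChouCounts(n_pos=1, n_neg=13, miss_pos=0, miss_neg=1)

    def test_all_zero(self):
        assert confusion_to_chou(ConfusionCounts(0, 0, 0, 0)) == ChouCounts(0, 0, 0, 0)

    def test_roundtrip_exhaustive_small(self):
        for n_pos in range(11):
            for n_neg in range(11):
                for miss_pos in range(n_pos + 1):
                    for miss_neg in range(n_neg + 1):
                        chou = ChouCounts(n_pos, n_neg, miss_pos, miss_neg)
                        assert confusion_to_chou(chou_to_confusion(chou)) == chou

    def test_invalid_counts_rejected(self):
        with pytest.raises(MetricsError):
            ChouCounts(n_pos=2, n_neg=5, miss_pos=3, miss_neg=0)
        with pytest.raises(MetricsError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestChouMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # the four published whole-protein scan examples
            (ChouCounts(1, 13, 0, 1), (1.00, 0.92, 0.93, 0.68)),
            (ChouCounts(3, 15, 0, 0), (1.00, 1.00, 1.00, 1.00)),
            (ChouCounts(1, 10, 0, 2), (1.00, 0.80, 0.82, 0.52)),
            (ChouCounts(11, 2, 0, 1), (1.00, 0.50, 0.92, 0.68)),
        ],
    )
    def test_worked_examples_two_decimals(self, counts, expected):
        m = chou_metrics(counts)
        assert (round(m.sn, 2), round(m.sp, 2), round(m.acc, 2), round(m.mcc, 2)) == expected

    def test_half_error_is_random_level(self):
        m = chou_metrics(ChouCounts(10, 20, 5, 10))
        assert m.acc == pytest.approx(0.5)
        assert m.mcc == pytest.approx(0.0)

    def test_limit_cases(self):
        perfect = chou_metrics(ChouCounts(5, 9, 0, 0))
        assert (perfect.sn, perfect.sp, perfect.acc, perfect.mcc) == (1, 1, 1, 1)
        inverted = chou_metrics(ChouCounts(5, 9, 5, 9))
        assert inverted.acc == pytest.approx(0.0)
        assert inverted.mcc == pytest.approx(-1.0)

    def test_empty_class_markers(self):
        no_pos = chou_metrics(ChouCounts(0, 5, 0, 1))
        assert no_pos.sn is None and no_pos.sp is not None
        no_neg = chou_metrics(ChouCounts(5, 0, 1, 0))
        assert no_neg.sp is None and no_neg.sn is not None

    def test_single_class_prediction_mcc_zero(self):
        # everything called positive: TN + FN = 0
        m = chou_metrics(ChouCounts(n_pos=4, n_neg=6, miss_pos=0, miss_neg=6))
        assert m.mcc == 0.0

    def test_exhaustive_equivalence_with_textbook_oracle(self):
        """Both metric parameterizations agree for every confusion table with
        class totals up to 30 (the two MCC forms are algebraically identical)."""
        for n_pos in range(1, 31):
            for n_neg in range(1, 31):
                for miss_pos in range(n_pos + 1):
                    for miss_neg in range(n_neg + 1):
                        m = chou_metrics(ChouCounts(n_pos, n_neg, miss_pos, miss_neg))
                        tp, fn = n_pos - miss_pos, miss_pos
                        tn, fp = n_neg - miss_neg, miss_neg
                        sn, sp, acc, mcc = textbook_metrics(tp, tn, fp, fn)
                        assert abs(m.sn - sn) < 1e-12
                        assert abs(m.sp - sp) < 1e-12
                        assert abs(m.acc - acc) < 1e-12
                        assert abs(m.mcc - mcc) < 1e-12
                        assert -1.0 <= m.mcc <= 1.0
                        assert 0.0 <= m.acc <= 1.0


class TestAverageReports:
    def test_published_table_rows_average(self):
        arg_acc = [72.16, 78.65, 73.24, 78.71, 77.30, 75.68, 77.57]
        lys_acc = [73.36, 65.01, 71.11, 67.27, 73.76, 72.23, 72.46]
        arg = [MetricSet(sn=None, sp=None, acc=a, mcc=None) for a in arg_acc]
        lys = [MetricSet(sn=None, sp=None, acc=a, mcc=None) for a in lys_acc]
        assert round(average_reports(arg).acc, 2) == 76.19
        assert round(average_reports(lys).acc, 2) == 70.74

    def test_single_report_is_identity(self):
        m = MetricSet(sn=0.7, sp=0.8, acc=0.75, mcc=0.5)
        a = average_reports([m])
        assert (a.sn, a.sp, a.acc, a.mcc) == (0.7, 0.8, 0.75, 0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(MetricsError):
            average_reports([])

    def test_none_propagates(self):
        a = average_reports(
            [MetricSet(0.5, 0.5, 0.5, 0.0), MetricSet(None, 0.7, 0.6, 0.1)]
        )
        assert a.sn is None
        assert a.sp == pytest.approx(0.6)


def blob_data(rng, n_per_class, gap):
    mu = np.zeros(N_FEATURES)
    mu[:8] = gap
    X = np.vstack(
        [
            rng.normal(0, 0.5, size=(n_per_class, N_FEATURES)) + mu,
            rng.normal(0, 0.5, size=(n_per_class, N_FEATURES)),
        ]
    )
    y = np.concatenate([np.ones(n_per_class, int), -np.ones(n_per_class, int)])
    return X, y


class TestJackknife:
    def test_every_sample_tested_once(self, rng):
        X, y = blob_data(rng, 6, gap=3.0)
        pred = loo_predictions(X, y, c=8.0, gamma=2.0 ** -3)
        assert pred.shape == y.shape  # one prediction per sample
        assert set(np.unique(pred)) <= {-1, 1}

    def test_separable_balanced_set_perfect(self, rng):
        X, y = blob_data(rng, 10, gap=5.0)
        m = jackknife_evaluate(X, y, c=8.0, gamma=2.0 ** -6)
        assert m.acc == 1.0

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = blob_data(r, 12, gap=4.0)
            y_shuffled = r.permutation(y)
            m = jackknife_evaluate(X, y_shuffled, c=8.0, gamma=2.0 ** -8)
            accs.append(m.acc)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_too_small_dataset(self):
        with pytest.raises(MetricsError):
            loo_predictions(np.zeros((1, N_FEATURES)), np.array([1]), 1.0, 0.1)

    def test_counts_from_predictions(self):
        y = np.array([1, 1, -1, -1, -1])
        pred = np.array([1, -1, -1, 1, -1])
        assert counts_from_predictions(y, pred) == ChouCounts(2, 3, 1, 1)


class TestBalancedJackknifeReport:
    def test_report_structure_and_average(self, rng, tmp_path):
        X_pos, _ = blob_data(rng, 8, gap=5.0)
        X_pos = X_pos[:8]
        subsets = [rng.normal(0, 0.5, size=(8, N_FEATURES)) for _ in range(3)]
        report = run_balanced_jackknife(X_pos, subsets, c=8.0, gamma=2.0 ** -3)
        assert isinstance(report, JackknifeReport)
        assert len(report.per_subset) == 3
        assert report.subset_sizes == [8, 8, 8]
        assert report.averaged.acc == pytest.approx(
            np.mean([m.acc for m in report.per_subset])
        )
        out = tmp_path / "report.tsv"
        write_report_tsv(report, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 + 3 + 1  # header, three subsets, average
        assert lines[-1].startswith("Average")
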