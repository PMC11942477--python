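"""Confusion-count metrics, AUROC/AUPRC, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnaduet.metrics import (ConfusionCounts, acc, auprc, auroc,
                             binary_confusion, mcc, metric_report,
                             pair_confusion, ppv_sen_f1, write_report)
from rnaduet.structure import pairs_to_matrix


class TestPairConfusion:
    def test_identity_prediction(self):
        truth = pairs_to_matrix({(0, 8), (1, 7)}, 9)
        c = pair_confusion(truth, truth)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_empty_prediction(self):
        truth = pairs_to_matrix({(0, 8), (1, 7)}, 9)
        c = pair_confusion(pairs_to_matrix(set(), 9), truth)
        assert (c.tp, c.fp, c.fn) == (0, 0, 2)

    def test_partial_overlap(self):
        pred = pairs_to_matrix({(0, 3)}, 4)
        truth = pairs_to_matrix({(0, 3), (1, 2)}, 4)
        c = pair_confusion(pred, truth)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_confusion(pairs_to_matrix(set(), 4), pairs_to_matrix(set(), 5))


class TestClosedForms:
    def test_hand_computed_ppv_sen_f1(self):
        ppv, sen, f1 = ppv_sen_f1(ConfusionCounts(3, 1, 2))
        assert ppv == pytest.approx(0.75)
        assert sen == pytest.approx(0.6)
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert f1 == pytest.approx(0.6667, abs=1e-4)

    def test_perfect_and_degenerate(self):
        assert ppv_sen_f1(ConfusionCounts(5, 0, 0)) == (1.0, 1.0, 1.0)
        assert ppv_sen_f1(ConfusionCounts(0, 3, 2)) == (0.0, 0.0, 0.0)

    def test_mcc_extremes(self):
        assert mcc(ConfusionCounts(4, 0, 0, tn=4)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(0, 1, 1, tn=0)) == pytest.approx(-1.0)
        assert mcc(ConfusionCounts(3, 2, 0, tn=0)) == 0.0  # one-class prediction

    def test_acc_hand_value(self):
        assert acc(ConfusionCounts(2, 1, 4, tn=3)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            acc(ConfusionCounts(0, 0, 0, tn=0))

    def test_tn_required(self):
        with pytest.raises(ValueError):
            mcc(ConfusionCounts(1, 1, 1))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40))
    def test_f1_between_ppv_and_sen(self, tp, fp, fn, tn):
        ppv, sen, f1 = ppv_sen_f1(ConfusionCounts(tp, fp, fn, tn))
        if ppv > 0 and sen > 0:
            assert min(ppv, sen) - 1e-12 <= f1 <= max(ppv, sen) + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_mcc_symmetric_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=50).astype(bool)
        b = rng.integers(0, 2, size=50).astype(bool)
        assert mcc(binary_confusion(a, b)) == pytest.approx(
            mcc(binary_confusion(b, a)))


class TestRecountOracle:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_random_pair_matrices(self, seed):
        rng = np.random.default_rng(seed)
        L = 20
        pred = np.triu(rng.random((L, L)) < 0.1, 1)
        truth = np.triu(rng.random((L, L)) < 0.1, 1)
        c = binary_confusion(pred, truth)
        # naive per-element recount
        tp = fp = fn = tn = 0
        for i in range(L):
            for j in range(L):
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestRankMetrics:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_equal_scores_mid_rank(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_auprc_ties_equal_prevalence(self):
        labels = [0, 1, 0, 1, 0, 0, 0, 1]
        assert auprc([0.5] * 8, labels) == pytest.approx(3 / 8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            return
        base = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(base)
        assert auroc(3 * scores - 7, labels) == pytest.approx(base)


class TestReport:
    def test_names_and_files(self, tmp_path):
        c = ConfusionCounts(3, 1, 2, tn=4)
        report = metric_report(c, scores=[0.1, 0.9, 0.8], labels=[0, 1, 1])
        assert set(report) == {"PPV", "SEN", "F1", "MCC", "ACC",
                               "AUROC", "AUPRC"}
        write_report(report, tmp_path / "r.json")
        assert (tmp_path / "r.json").exists()
        assert (tmp_path / "r.tsv").exists()
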