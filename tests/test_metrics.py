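"""Evaluation metrics and consensus utilities against brute-force oracles."""

import numpy as np
import pytest
from oracles import (auc_concordance_loop, average_precision_pr_loop,
                     kappa_by_hand)

from tonguedx import metrics as m


class TestClassificationMetrics:
    def test_hand_computed_confusion_example(self):
        rep = m.classification_metrics(m.ConfusionCounts(tp=50, tn=30, fp=10, fn=10))
        assert rep["acc"] == pytest.approx(0.8)
        assert rep["precision"] == pytest.approx(50 / 60)
        assert rep["recall"] == pytest.approx(50 / 60)
        assert rep["f1"] == pytest.approx(50 / 60)

    def test_perfect_predictor_scores_one_everywhere(self):
        rep = m.classification_metrics(m.ConfusionCounts(tp=40, tn=60, fp=0, fn=0))
        assert all(rep[k] == 1.0 for k in ("acc", "precision", "recall", "f1"))

    def test_multilabel_batch_matches_counting_oracle(self, rng):
        t = (rng.random((40, 6)) < 0.4).astype(int)
        p = (rng.random((40, 6)) < 0.5).astype(int)
        per = [m.confusion_counts(t[:, j], p[:, j]) for j in range(6)]
        rep = m.classification_metrics(per)
        f1s = []
        for j in range(6):
            tp = int(((t[:, j] == 1) & (p[:, j] == 1)).sum())
            fp = int(((t[:, j] == 0) & (p[:, j] == 1)).sum())
            fn = int(((t[:, j] == 1) & (p[:, j] == 0)).sum())
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert rep["f1"] == pytest.approx(np.mean(f1s))

    def test_macro_f1_invariant_under_label_permutation(self, rng):
        t = (rng.random((30, 5)) < 0.4).astype(int)
        p = (rng.random((30, 5)) < 0.5).astype(int)
        perm = rng.permutation(5)
        rep1 = m.classification_metrics(
            [m.confusion_counts(t[:, j], p[:, j]) for j in range(5)])
        rep2 = m.classification_metrics(
            [m.confusion_counts(t[:, j], p[:, j]) for j in perm])
        assert rep1["f1"] == pytest.approx(rep2["f1"])

    def test_micro_averaging_pools_counts(self):
        per = [m.ConfusionCounts(10, 5, 3, 2), m.ConfusionCounts(1, 17, 1, 1)]
        rep = m.classification_metrics(per, averaging="micro")
        assert rep["precision"] == pytest.approx(11 / 15)
        assert rep["recall"] == pytest.approx(11 / 14)

    def test_zero_denominator_flagged(self):
        rep = m.classification_metrics(m.ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert rep["degenerate"] and rep["precision"] == 0.0


class TestAveragePrecision:
    def test_perfect_ranking_gives_one(self):
        assert m.average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_pr_curve_example(self):
        # hits at ranks 1 and 3: AP = (1/1 + 2/3)/2
        ap = m.average_precision([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert ap == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)

    def test_matches_all_threshold_pr_oracle(self, rng):
        for _ in range(30):
            scores = rng.random(25)
            targets = (rng.random(25) < 0.4).astype(int)
            if targets.sum() == 0:
                continue
            assert m.average_precision(scores, targets) == pytest.approx(
                average_precision_pr_loop(scores, targets))

    def test_map_skips_positive_free_classes(self, rng):
        scores = rng.random((10, 3))
        targets = np.zeros((10, 3), dtype=int)
        targets[:4, 0] = 1
        val, skipped = m.map_score(scores, targets)
        assert skipped == [1, 2]

    def test_no_positives_anywhere_raises(self):
        with pytest.raises(ValueError):
            m.map_score(np.random.rand(5, 2), np.zeros((5, 2)))


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert m.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert m.auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_matches_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)  # ties occur
            targets = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(targets)) < 2:
                continue
            assert m.auc(scores, targets) == pytest.approx(
                auc_concordance_loop(scores, targets))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="classes"):
            m.auc([0.1, 0.9], [1, 1])


class TestCohensKappa:
    def test_identical_annotations_give_one(self):
        a = np.array([0, 1, 1, 0, 1])
        assert m.cohens_kappa(a, a) == 1.0

    def test_hand_computed_two_rater_example(self):
        # counts: both-yes 20, both-no 60, a-only 10, b-only 10
        # p_o = 0.8; marginals 0.3/0.3 -> p_e = 0.09 + 0.49 = 0.58
        # kappa = (0.8 - 0.58)/(1 - 0.58) = 11/21
        a = np.array([1] * 20 + [0] * 60 + [1] * 10 + [0] * 10)
        b = np.array([1] * 20 + [0] * 60 + [0] * 10 + [1] * 10)
        assert m.cohens_kappa(a, b) == pytest.approx(11 / 21)
        assert m.cohens_kappa(a, b) == pytest.approx(kappa_by_hand(a, b))

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(7)
        a = (rng.random(10**4) < 0.5).astype(int)
        b = (rng.random(10**4) < 0.5).astype(int)
        assert abs(m.cohens_kappa(a, b)) < 0.05

    def test_matches_hand_formula_on_random_data(self, rng):
        a = rng.integers(0, 3, size=200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, size=200))
        assert m.cohens_kappa(a, b) == pytest.approx(kappa_by_hand(a, b))


class TestConsensus:
    def test_three_identical_vectors_kept(self):
        v = np.array([1, 0, 1])
        assert m.consensus_filter((v, v.copy(), v.copy()))

    def test_single_label_disagreement_discarded(self):
        v = np.array([1, 0, 1])
        w = v.copy()
        w[2] = 0
        assert not m.consensus_filter((v, v.copy(), w))

    def test_batch_keeps_exactly_unanimous_triples(self, rng):
        kept = 0
        expected = 0
        for _ in range(50):
            a = (rng.random(5) < 0.5).astype(int)
            b = a.copy() if rng.random() < 0.6 else (rng.random(5) < 0.5).astype(int)
            c = a.copy() if rng.random() < 0.6 else (rng.random(5) < 0.5).astype(int)
            unanimous = np.array_equal(a, b) and np.array_equal(b, c)
            expected += unanimous
            kept += m.consensus_filter((a, b, c))
        assert kept == expected

    def test_kept_data_has_unit_pairwise_kappa(self, rng):
        labels = (rng.random((30, 4)) < 0.5).astype(int)
        assert m.multilabel_kappa(labels, labels.copy()) == 1.0


class TestAuditSample:
    def test_ten_percent_of_hundred_is_ten(self):
        assert len(m.audit_sample(list(range(100)), 0.10, seed=1)) == 10

    def test_full_fraction_returns_all(self):
        ids = list(range(17))
        assert sorted(m.audit_sample(ids, 1.0, seed=3)) == ids

    def test_seed_determinism(self):
        ids = list(range(50))
        assert m.audit_sample(ids, 0.2, seed=9) == m.audit_sample(ids, 0.2, seed=9)

    def test_empty_input_gives_empty_output(self):
        assert m.audit_sample([], 0.5, seed=0) == []
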