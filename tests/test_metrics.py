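import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snapqsar import metrics as mx


def _random_instance(rng, n, ties=False):
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    if ties:
        probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
    else:
        probs = rng.random(n)
    return probs, labels


class TestContingency:
    def test_basic(self):
        t = mx.contingency([0.9, 0.1], [1, 0], 0.5)
        assert (t.tp, t.fp, t.tn, t.fn) == (1, 0, 1, 0)

    def test_cutoff_zero_all_positive(self):
        t = mx.contingency([0.2, 0.8, 0.5], [0, 1, 0], 0.0)
        assert t.fp == 2
        assert t.tn == 0

    def test_counts_sum_to_n(self, rng):
        probs, labels = _random_instance(rng, 50)
        t = mx.contingency(probs, labels, 0.4)
        assert t.total == 50

    def test_matches_elementwise_loop(self, rng):
        probs, labels = _random_instance(rng, 50)
        t = mx.contingency(probs, labels, 0.37)
        tp = fp = tn = fn = 0  # independent per-item oracle
        for p, y in zip(probs, labels):
            if p >= 0.37:
                tp, fp = tp + (y == 1), fp + (y == 0)
            else:
                tn, fn = tn + (y == 0), fn + (y == 1)
        assert (t.tp, t.fp, t.tn, t.fn) == (tp, fp, tn, fn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mx.contingency([0.5], [1, 0], 0.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mx.ContingencyTable(-1, 0, 0, 0)


class TestBasicMetrics:
    def test_arithmetic_oracle(self):
        r = mx.basic_metrics(mx.ContingencyTable(tp=3, fp=1, tn=4, fn=2))
        assert r.sensitivity == pytest.approx(0.6)
        assert r.specificity == pytest.approx(0.8)
        assert r.bac == pytest.approx(0.7)
        assert r.acc == pytest.approx(0.7)
        assert r.precision == pytest.approx(0.75)
        assert r.f_measure == pytest.approx(2 * 0.6 * 0.75 / 1.35)
        assert r.mcc == pytest.approx(
            (3 * 4 - 1 * 2) / np.sqrt(4 * 5 * 5 * 6))
        assert r.mcc == pytest.approx(0.4082, abs=5e-5)

    def test_perfect_classifier(self):
        r = mx.basic_metrics(mx.ContingencyTable(tp=5, fp=0, tn=7, fn=0))
        for name in ("sensitivity", "specificity", "bac", "acc", "precision",
                     "f_measure", "mcc"):
            assert getattr(r, name) == pytest.approx(1.0)

    def test_degenerate_sensitivity_flagged(self):
        r = mx.basic_metrics(mx.ContingencyTable(tp=0, fp=2, tn=3, fn=0))
        assert r.sensitivity == 0.0
        assert "sensitivity" in r.degenerate_flags

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mx.basic_metrics(mx.ContingencyTable(0, 0, 0, 0))

    @given(tp=st.integers(0, 200), fp=st.integers(0, 200),
           tn=st.integers(0, 200), fn=st.integers(0, 200))
    @settings(max_examples=500)
    def test_bac_identity_and_mcc_range(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = mx.basic_metrics(mx.ContingencyTable(tp, fp, tn, fn))
        assert r.bac == (r.sensitivity + r.specificity) / 2
        assert -1.0 - 1e-12 <= r.mcc <= 1.0 + 1e-12
        for name in ("sensitivity", "specificity", "bac", "acc", "precision",
                     "recall", "f_measure"):
            assert 0.0 <= getattr(r, name) <= 1.0

    def test_mcc_swap_symmetry(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, 4)
            a = mx.basic_metrics(mx.ContingencyTable(tp, fp, tn, fn)).mcc
            b = mx.basic_metrics(mx.ContingencyTable(tn, fn, tp, fp)).mcc
            assert a == pytest.approx(b)

    def test_mcc_label_inversion_negates(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, 4)
            a = mx.basic_metrics(mx.ContingencyTable(tp, fp, tn, fn)).mcc
            b = mx.basic_metrics(mx.ContingencyTable(fn, tn, fp, tp)).mcc
            assert a == pytest.approx(-b)


def _youden_scan_oracle(probs, labels):
    """Exhaustive scan over every cutoff in a fine value grid."""
    candidates = sorted(set(np.concatenate([probs, [0.0, 1.0],
                                            probs - 1e-9, probs + 1e-9])))
    best = (-np.inf, None)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for c in candidates:
        pred = probs >= c
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, c)
    return best[0]


class TestYoudenCutoff:
    def test_perfect_separation(self):
        cutoff, j = mx.youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert j == pytest.approx(1.0)
        assert 0.2 < cutoff < 0.8

    def test_uninformative_scores_give_small_j(self, rng):
        probs = rng.random(400)
        labels = rng.integers(0, 2, 400)
        _, j = mx.youden_cutoff(probs, labels)
        assert j < 0.2

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            probs, labels = _random_instance(rng, 20, ties=True)
            cutoff, j = mx.youden_cutoff(probs, labels)
            assert j == pytest.approx(_youden_scan_oracle(probs, labels))

    def test_j_equals_max_tpr_minus_fpr(self, rng):
        probs, labels = _random_instance(rng, 40)
        _, j = mx.youden_cutoff(probs, labels)
        best = max(tpr - fpr for _, fpr, tpr
                   in mx.roc_curve_points(probs, labels))
        assert j == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mx.youden_cutoff([0.1, 0.9], [1, 1])


def _roc_pair_oracle(probs, labels):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect(self):
        assert mx.roc_auc([0.1, 0.9], [0, 1]) == 1.0

    def test_all_ties_half(self):
        assert mx.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_pair_counting_oracle(self, rng):
        for _ in range(20):
            probs, labels = _random_instance(rng, 30, ties=rng.random() < 0.5)
            assert mx.roc_auc(probs, labels) == pytest.approx(
                _roc_pair_oracle(probs, labels), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        probs, labels = _random_instance(rng, 40)
        assert mx.roc_auc(probs ** 3, labels) == pytest.approx(
            mx.roc_auc(probs, labels), abs=1e-12)

    def test_label_inversion(self, rng):
        probs, labels = _random_instance(rng, 40)
        assert mx.roc_auc(probs, 1 - labels) == pytest.approx(
            1.0 - mx.roc_auc(probs, labels), abs=1e-12)

    def test_single_class_convention(self):
        flags = []
        assert mx.roc_auc([0.2, 0.8], [0, 0], flags) == 0.5
        assert flags == ["roc_auc"]

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            probs, labels = _random_instance(rng, 50, ties=True)
            assert mx.roc_auc(probs, labels) == pytest.approx(
                roc_auc_score(labels, probs), abs=1e-12)


def _pr_threshold_oracle(probs, labels):
    """Brute-force threshold enumeration of average precision."""
    n_pos = labels.sum()
    thresholds = sorted(set(probs), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = probs >= t
        tp = np.sum(pred & (labels == 1))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestPrAuc:
    def test_perfect(self):
        assert mx.pr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_threshold_oracle(self, rng):
        for _ in range(20):
            probs, labels = _random_instance(rng, 20, ties=rng.random() < 0.5)
            assert mx.pr_auc(probs, labels) == pytest.approx(
                _pr_threshold_oracle(probs, labels), abs=1e-12)

    def test_independent_scores_approach_prevalence(self):
        rng = np.random.default_rng(123)
        n = 10_000
        labels = (rng.random(n) < 0.3).astype(int)
        probs = rng.random(n)
        prevalence = labels.mean()
        assert mx.pr_auc(probs, labels) == pytest.approx(prevalence, abs=0.03)

    def test_no_positives_flagged(self):
        flags = []
        assert mx.pr_auc([0.2, 0.8], [0, 0], flags) == 0.0
        assert flags == ["pr_auc"]

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            probs, labels = _random_instance(rng, 50, ties=True)
            assert mx.pr_auc(probs, labels) == pytest.approx(
                average_precision_score(labels, probs), abs=1e-12)


class TestFullReport:
    def test_perfectly_separated(self):
        r = mx.full_report([0.05, 0.1, 0.9, 0.95], [0, 0, 1, 1])
        assert r.roc_auc == 1.0
        assert r.bac == 1.0
        assert r.mcc == 1.0
        assert r.youden_j == pytest.approx(1.0)

    def test_all_negative_labels_degenerate(self):
        r = mx.full_report([0.2, 0.8], [0, 0])
        assert r.roc_auc == 0.5
        assert "roc_auc" in r.degenerate_flags
        assert "pr_auc" in r.degenerate_flags

    def test_explicit_cutoff_respected(self):
        r = mx.full_report([0.3, 0.45, 0.7], [0, 1, 1], cutoff=0.4)
        assert r.cutoff == 0.4
        assert r.sensitivity == 1.0
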