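"""Metrics, ROC/AUC, paired t-tests and Holm correction against oracles."""

import numpy as np
import pytest
from scipy import stats

from osfpnet import (
    ConfusionCounts,
    confusion,
    holm_bonferroni,
    metrics,
    paired_t_test,
    roc_auc,
)


class TestConfusion:
    def test_hand_enumerated_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert c.fp == c.fn == 0 and c.tp == 2 and c.tn == 2

    def test_all_positive_on_all_negative(self):
        c = confusion([0, 0, 0], [1, 1, 1])
        assert c.tp == c.tn == 0 and c.fp == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [1])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [0, 1])

    def test_counts_total_matches_n(self, rng):
        # brute-force recount oracle on random vectors
        for _ in range(200):
            n = int(rng.integers(1, 100))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            c = confusion(y, p)
            assert c.total == n
            assert c.tp == sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            assert c.tn == sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            assert c.fp == sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            assert c.fn == sum(1 for a, b in zip(y, p) if a == 1 and b == 0)


class TestMetrics:
    def test_direct_substitution_example(self):
        m = metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        for name, v in m.as_dict().items():
            assert v == pytest.approx(0.5), name

    def test_perfect_classifier_all_ones(self):
        m = metrics(ConfusionCounts(tp=3, fp=0, tn=5, fn=0))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_undefined_denominators_flagged_not_zeroed(self):
        # no predicted positives and no actual positives: precision undefined
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m.precision is None and "precision" in m.undefined
        assert m.sensitivity is None  # no positives at all
        assert m.specificity == 1.0 and m.accuracy == 1.0

    def test_zero_sensitivity_with_positives_present(self):
        m = metrics(ConfusionCounts(tp=0, fp=2, tn=2, fn=3))
        assert m.sensitivity == 0.0 and m.precision == 0.0
        # F1 = 0/0 here: undefined, not silently 0
        assert m.f1 is None and "f1" in m.undefined

    def test_formulas_on_random_counts(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 30, 4))
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.precision == pytest.approx(tp / (tp + fp))
            assert m.f1 == pytest.approx(
                2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
            )


def _pair_ordering_auc(labels, scores):
    """Brute-force Mann-Whitney oracle: fraction of correctly ordered
    (positive, negative) pairs, ties counted half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_auc_1(self):
        r = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert r.auc == pytest.approx(1.0)

    def test_fpr_tpr_are_curves_from_0_to_1(self):
        r = roc_auc([0, 1, 0, 1, 1], [0.3, 0.2, 0.5, 0.9, 0.6])
        assert r.fpr[0] == 0.0 and r.fpr[-1] == 1.0
        assert r.tpr[0] == 0.0 and r.tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_equals_pair_ordering_fraction(self, rng):
        # Mann-Whitney identity on n <= 50, including ties
        for trial in range(50):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces score ties
            r = roc_auc(labels, scores)
            assert r.auc == pytest.approx(_pair_ordering_auc(labels, scores))

    def test_random_scores_give_chance_auc(self, rng):
        # Hanley-McNeil: SE of AUC ~ sqrt(A(1-A)... ) ~ 1/sqrt(12) scaling;
        # use the Mann-Whitney normal SE at AUC=0.5
        n_pos = n_neg = 300
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        scores = rng.random(n_pos + n_neg)
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(roc_auc(labels, scores).auc - 0.5) < 3 * se


class TestPairedT:
    def test_identical_series_degenerate(self):
        r = paired_t_test([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert r.degenerate and r.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.degenerate and r.p_value == 0.0

    def test_matches_textbook_computation(self):
        a = [0.9, 0.8, 0.95, 0.85, 0.9]
        b = [0.7, 0.75, 0.8, 0.72, 0.78]
        d = np.array(a) - np.array(b)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        r = paired_t_test(a, b)
        assert not r.degenerate
        assert r.statistic == pytest.approx(t)
        assert r.p_value == pytest.approx(p)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test([1.0], [0.5])


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.03]), [0.03])

    def test_direct_stepdown_example(self):
        # k-th smallest multiplied by (N - k + 1): 3*0.01, 2*0.02, 1*0.04
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_returned_in_input_order(self):
        out = holm_bonferroni([0.04, 0.01, 0.02])
        np.testing.assert_allclose(out, [0.04, 0.03, 0.04])

    def test_monotone_enforcement_and_cap(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 10)))
            out = holm_bonferroni(p)
            assert (out >= p - 1e-12).all() and (out <= 1.0).all()
            order = np.argsort(p)
            assert (np.diff(out[order]) >= -1e-12).all()

    def test_direct_formula_oracle_with_monotone_max(self, rng):
        for _ in range(50):
            p = np.round(rng.random(6), 3)
            order = np.argsort(p, kind="stable")
            n = len(p)
            raw = [(n - k) * p[order[k]] for k in range(n)]
            expected_sorted = np.minimum(np.maximum.accumulate(raw), 1.0)
            expected = np.empty(n)
            expected[order] = expected_sorted
            np.testing.assert_allclose(holm_bonferroni(p), expected, atol=1e-12)

    def test_never_rejects_more_than_uncorrected(self, rng):
        alpha = 0.05
        for _ in range(50):
            p = rng.random(8) * 0.2
            corrected = holm_bonferroni(p)
            assert (corrected < alpha).sum() <= (p < alpha).sum()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            holm_bonferroni([0.1, 1.2])
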