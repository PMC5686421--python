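"""Ranking-metric unit and oracle tests.

The brute-force oracles enumerate precision at each positive rank (AP) and
count concordant / tied positive-negative pairs (AUC) directly from the
definitions; the implementations must agree to near machine precision.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from termrank.datatypes import ConfigurationError
from termrank.evaluation import auc_roc, average_precision, paired_t_test


def brute_force_ap(labels, scores):
    """Precision-at-each-positive enumeration on the (stable) sorted order."""
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], i))
    ranked = [labels[i] for i in order]
    P = sum(ranked)
    total, hits = 0.0, 0
    for k, lab in enumerate(ranked, start=1):
        if lab == 1:
            hits += 1
            total += hits / k
    return total / P


def brute_force_auc(labels, scores):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAveragePrecision:
    @pytest.mark.parametrize(
        "ranked,expected",
        [
            ([1, 1, 0, 0], 1.0),
            ([1, 0, 1, 0], 5 / 6),
            ([0, 0, 1], 1 / 3),
        ],
    )
    def test_known_rankings(self, ranked, expected):
        # descending scores reproduce the given ranked label order
        scores = np.linspace(1, 0, len(ranked))
        assert average_precision(ranked, scores) == pytest.approx(expected, abs=1e-12)

    def test_no_positives_is_an_error(self):
        with pytest.raises(ConfigurationError):
            average_precision([0, 0], [0.1, 0.2])

    def test_tie_break_by_key(self):
        # equal scores: ascending term key decides the order deterministically
        labels = np.array([1, 0])
        scores = np.array([0.5, 0.5])
        ap_ba = average_precision(labels, scores, tie_keys=np.array(["b", "a"]))
        ap_ab = average_precision(labels, scores, tie_keys=np.array(["a", "b"]))
        assert ap_ab == 1.0 and ap_ba == 0.5

    def test_matches_brute_force_on_random_lists(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[rng.integers(n)] = 1
            scores = np.round(rng.random(n), 2)  # induce frequent ties
            got = average_precision(labels, scores)
            want = brute_force_ap(list(labels), list(scores))
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_sklearn_without_ties(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(50):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.normal(size=n)  # continuous: ties have measure zero
            assert average_precision(labels, scores) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-10
            )


class TestAucRoc:
    def test_perfect_and_degenerate(self):
        assert auc_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_roc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_known_interleaved(self):
        assert auc_roc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    def test_single_class_is_an_error(self):
        with pytest.raises(ConfigurationError):
            auc_roc([1, 1], [0.1, 0.2])

    def test_matches_brute_force_on_random_lists(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = np.round(rng.random(n), 2)
            got = auc_roc(labels, scores)
            want = brute_force_auc(list(labels), list(scores))
            assert got == pytest.approx(want, abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=4, max_size=40), st.data())
def test_metrics_invariant_under_monotone_score_transforms(labels, data):
    """AP and AUC depend only on the induced order of the scores."""
    n = len(labels)
    if sum(labels) in (0, n):
        labels[0] = 1 - labels[0]
        if sum(labels) in (0, n):
            labels[-1] = 1 - labels[-1]
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    scores = rng.normal(size=n)
    transformed = np.exp(3.0 * scores) + 7.0  # strictly increasing map
    assert average_precision(labels, scores) == pytest.approx(
        average_precision(labels, transformed), abs=1e-12
    )
    assert auc_roc(labels, scores) == pytest.approx(auc_roc(labels, transformed), abs=1e-12)


class TestPairedT:
    def test_identical_inputs(self):
        t, p, df = paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (t, p, df) == (0.0, 1.0, 2)

    def test_constant_nonzero_difference_is_capped(self):
        t, p, df = paired_t_test([1, 1, 1, 1], [0, 0, 0, 0])
        assert t > 1e100 and p < 1e-300 and df == 3

    def test_matches_textbook_formula(self):
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        b = np.zeros(6)
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t_expected), len(d) - 1)
        t, p, df = paired_t_test(a, b)
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert p == pytest.approx(p_expected, abs=1e-12)
        assert df == 5

    def test_too_short_is_an_error(self):
        with pytest.raises(ConfigurationError):
            paired_t_test([1.0], [0.0])
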