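"""Rank AUC, Mann-Whitney inference and report statistics against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sitelearn.errors import ValidationError
from sitelearn.stats import (
    auc_rank,
    bonferroni,
    hanley_mcneil_ci,
    mwu_auc_inference,
    secondary_metrics,
    site_size_performance_correlation,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    cases = scores[np.asarray(labels) == 1]
    controls = scores[np.asarray(labels) == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestAUC:
    def test_hand_examples(self):
        assert auc_rank([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75
        assert auc_rank([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 0.5
        assert auc_rank([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0]) == 1.0

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValidationError):
            auc_rank([1.0, 2.0], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_pairwise_enumeration(self, data):
        n1 = data.draw(st.integers(1, 12))
        n0 = data.draw(st.integers(1, 12))
        vals = data.draw(st.lists(st.integers(0, 6), min_size=n1 + n0,
                                  max_size=n1 + n0))
        labels = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
        assert auc_rank(vals, labels) == brute_force_auc(vals, labels)


class TestMWU:
    def test_exact_enumeration_example(self):
        u, p, _ = mwu_auc_inference([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert u == 9.0
        assert p == pytest.approx(2 / 20)  # 2 / C(6,3)

    def test_null_center_has_p_near_one(self):
        # ABBA rank pattern makes U hit its null mean exactly (AUC = 0.5)
        scores = np.arange(20, dtype=float)
        labels = np.array([1, 0, 0, 1] * 5)
        assert auc_rank(scores, labels) == 0.5
        _, p, _ = mwu_auc_inference(scores, labels)
        assert p == 1.0

    def test_p_decreases_as_auc_moves_from_half(self):
        n = 20
        controls = np.arange(n, dtype=float)
        ps, aucs = [], []
        for shift in (0.5, 2.5, 4.5, 8.5, 14.5):
            scores = np.r_[controls + shift, controls]
            labels = np.r_[np.ones(n), np.zeros(n)].astype(int)
            aucs.append(auc_rank(scores, labels))
            ps.append(mwu_auc_inference(scores, labels)[1])
        assert all(a < b for a, b in zip(aucs, aucs[1:]))  # strictly rising AUC
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            s = rng.normal(size=60)
            y = np.r_[np.ones(25), np.zeros(35)].astype(int)
            rng.shuffle(y)
            _, p, _ = mwu_auc_inference(s, y)
            ref = sps.mannwhitneyu(s[y == 1], s[y == 0],
                                   alternative="two-sided",
                                   method="asymptotic").pvalue
            assert p == pytest.approx(ref, abs=1e-10)

    def test_u_equals_auc_times_pair_count(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        y = np.r_[np.ones(10), np.zeros(20)].astype(int)
        u, _, _ = mwu_auc_inference(s, y)
        assert u == pytest.approx(auc_rank(s, y) * 10 * 20)

    def test_ci_brackets_auc_and_is_truncated(self):
        s = np.r_[np.arange(10) + 5.0, np.arange(10).astype(float)]
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        _, _, (lo, hi) = mwu_auc_inference(s, y)
        a = auc_rank(s, y)
        assert 0.0 <= lo <= a <= hi <= 1.0


class TestBonferroni:
    def test_threshold_with_thirty_comparisons(self):
        flags = bonferroni([0.001, 0.002], alpha=0.05, m=30)
        assert flags.tolist() == [True, False]  # 0.05/30 = 0.001667

    def test_m_one_reduces_to_uncorrected(self):
        assert bonferroni([0.04], alpha=0.05, m=1)[0]


class TestSecondaryMetrics:
    def test_perfect_and_antiperfect(self):
        y = [1, 1, 0, 0]
        bacc, sens, spec = secondary_metrics([0.9, 0.8, 0.2, 0.1], y, 0.5)
        assert (bacc, sens, spec) == (1.0, 1.0, 1.0)
        bacc, sens, spec = secondary_metrics([0.1, 0.2, 0.8, 0.9], y, 0.5)
        assert (bacc, sens, spec) == (0.0, 0.0, 0.0)

    def test_hand_count(self):
        bacc, sens, spec = secondary_metrics([0.9, 0.2, 0.8, 0.1],
                                             [1, 1, 0, 0], 0.5)
        assert (bacc, sens, spec) == (0.5, 0.5, 0.5)


class TestSiteSizeCorrelation:
    def test_monotone_and_antitone(self):
        rho, _ = site_size_performance_correlation([0.5, 0.6, 0.7], [10, 20, 30])
        assert rho == 1.0
        rho, _ = site_size_performance_correlation([0.7, 0.6, 0.5], [10, 20, 30])
        assert rho == -1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            site_size_performance_correlation([0.5, 0.5, 0.5], [10, 20, 30])

    def test_permutation_null_calibration(self):
        rng = np.random.default_rng(3)
        sizes = np.arange(1, 25, dtype=float)
        crit = 0
        n_rep = 400
        for _ in range(n_rep):
            aucs = rng.normal(size=24)
            _, p = site_size_performance_correlation(aucs, sizes)
            crit += p < 0.05
        assert 0.02 < crit / n_rep < 0.09


def test_hanley_mcneil_close_to_bootstrap():
    rng = np.random.default_rng(10)
    s = np.r_[rng.normal(1.0, 1, 40), rng.normal(0, 1, 40)]
    y = np.r_[np.ones(40), np.zeros(40)].astype(int)
    lo, hi = hanley_mcneil_ci(auc_rank(s, y), 40, 40)
    boots = []
    for _ in range(500):
        idx1 = rng.integers(0, 40, 40)
        idx0 = 40 + rng.integers(0, 40, 40)
        boots.append(auc_rank(np.r_[s[idx1], s[idx0]], y))
    b_lo, b_hi = np.percentile(boots, [2.5, 97.5])
    assert abs(lo - b_lo) < 0.06 and abs(hi - b_hi) < 0.06
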