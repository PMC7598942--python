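"""Permutation importance, BH selection and the cross-fold consistency rule."""

import numpy as np
import pytest

from sitelearn.errors import ContractError, ValidationError
from sitelearn.importance import (
    consistency_filter,
    fdr_bh,
    permutation_importance,
    run_fold_importance,
)
from sitelearn.models import ModelSpec


def _rfc(seed=0, trees=50):
    return ModelSpec("rfc", seed=seed, params={"n_estimators": trees})


class TestFdrBH:
    def test_step_up_hand_example(self):
        sel, q = fdr_bh([0.001, 0.02, 0.04, 0.8], q=0.05)
        assert sel.tolist() == [True, True, False, False]
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04 * 4 / 3, 0.8])

    def test_all_ones_none_selected(self):
        sel, _ = fdr_bh([1.0, 1.0, 1.0])
        assert not sel.any()

    def test_single_p_reduces_to_raw_threshold(self):
        sel, _ = fdr_bh([0.04], q=0.05)
        assert sel[0]

    def test_qvalues_monotone_and_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-4, 1, 50)
        _, q = fdr_bh(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_zero_p_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.0, 0.5])

    def test_matches_statsmodels_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-5, 1, int(rng.integers(3, 80)))
            sel, q = fdr_bh(p, q=0.05)
            ref_sel, ref_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, ref_q, rtol=1e-12)
            np.testing.assert_array_equal(sel, ref_sel)


class TestConsistency:
    def test_strict_majority(self):
        sel = np.zeros((10, 3), dtype=bool)
        sel[:5, 0] = True   # 5 of 10 -> not consistent (strict)
        sel[:6, 1] = True   # 6 of 10 -> consistent
        sel[:, 2] = True    # 10 of 10 -> consistent
        out = consistency_filter(sel)
        assert out.tolist() == [False, True, True]

    def test_needs_two_folds(self):
        with pytest.raises(ValidationError):
            consistency_filter(np.zeros((1, 3), dtype=bool))


class TestPermutationImportance:
    def test_informative_feature_hits_p_floor(self):
        rng = np.random.default_rng(1)
        n, p = 80, 12
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        X = rng.normal(size=(n, p))
        X[:, 0] = y + rng.normal(scale=0.05, size=n)  # label plus tiny noise
        obs, pv = permutation_importance(X, y, _rfc(), B=100, seed=2)
        assert pv[0] == pytest.approx(1 / 101)  # minimum attainable
        assert obs[0] > obs[1:].max()

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        n, p = 60, 10
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        pv_all = []
        for rep in range(3):
            X = rng.normal(size=(n, p))
            _, pv = permutation_importance(X, y, _rfc(seed=rep), B=60,
                                           seed=rep)
            pv_all.extend(pv)
        stat = sps.kstest(pv_all, "uniform")
        assert stat.pvalue > 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        _, p1 = permutation_importance(X, y, _rfc(), B=60, seed=9)
        _, p2 = permutation_importance(X, y, _rfc(), B=60, seed=9)
        np.testing.assert_array_equal(p1, p2)

    def test_small_B_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.raises(ValidationError):
            permutation_importance(X, y, _rfc(), B=20)

    def test_non_rfc_spec_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.raises(ContractError):
            permutation_importance(X, y, ModelSpec("xgb"), B=100)

    def test_p_floor_never_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 4))
        X[:, 0] += 3.0 * np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        _, pv = permutation_importance(X, y, _rfc(), B=50, seed=0)
        assert pv.min() >= 1 / 51


class TestFoldWorkflow:
    def test_signal_recovery_with_small_feature_panel(self):
        """With m=30 features the BH entry threshold (q*i/m) clears the
        p-value floor 1/(B+1), so injected features are selected and pass
        the >50%-of-folds consistency rule."""
        rng = np.random.default_rng(7)
        n, p_inf, p_null = 100, 5, 25
        names = [f"f{j}" for j in range(p_inf + p_null)]
        mats = []
        for fold in range(4):
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
            X = rng.normal(size=(n, p_inf + p_null))
            X[:, :p_inf] += 2.0 * y[:, None]
            mats.append((X, y))
        res = run_fold_importance(mats, names, _rfc(), B=200, seed=4)
        assert res.consistent[:p_inf].all()
        false_disc = res.consistent[p_inf:].sum()
        assert false_disc <= 2

    def test_covariate_columns_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        with pytest.raises(ContractError, match="covariate"):
            run_fold_importance([(X, y), (X, y)], ["a", "b", "c"], _rfc(), B=60)
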