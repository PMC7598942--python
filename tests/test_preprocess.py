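"""Exclusion, train-median imputation, robust scaling, regime assembly."""

import numpy as np
import pandas as pd
import pytest

from sitelearn.errors import ContractError, SchemaError, ValidationError
from sitelearn.preprocess import (
    apply_preprocess,
    assemble_features,
    covariate_block,
    exclude_high_missingness,
    fit_preprocess,
)
from sitelearn.table import SubjectTable

from conftest import make_toy_table


def _table_with_feature(values, mask=None):
    n = len(values)
    meta = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "site_id": "site0",
        "diagnosis": [i % 2 for i in range(n)],
        "age": np.linspace(20, 40, n),
        "sex": ["M"] * n,
    })
    feats = pd.DataFrame({"f": np.asarray(values, dtype=float)})
    if mask:
        for i in mask:
            feats.iat[i, 0] = np.nan
    return SubjectTable(meta, feats)


class TestExclusion:
    @pytest.mark.parametrize("n_missing,kept", [(16, False), (15, True), (0, True)])
    def test_ten_percent_threshold_is_strict(self, n_missing, kept):
        # 16/157 = 10.19% excluded; 15/157 = 9.55% retained
        t = make_toy_table(n=6, p=157,
                           missing=[(0, j) for j in range(n_missing)])
        out, report = exclude_high_missingness(t, threshold=0.10)
        assert ("s000" in set(out.meta["subject_id"])) == kept
        assert len(report) == (0 if kept else 1)

    def test_all_excluded_raises(self):
        t = make_toy_table(n=3, p=4, missing=[(i, j) for i in range(3)
                                              for j in range(4)])
        with pytest.raises(ValidationError):
            exclude_high_missingness(t)


class TestRobustScaling:
    def test_median_and_iqr_on_1_to_5(self):
        t = _table_with_feature([1, 2, 3, 4, 5])
        state = fit_preprocess(t)
        assert state.medians[0] == 3.0
        assert state.iqrs[0] == 2.0  # Q1=2, Q3=4 by linear interpolation
        out = apply_preprocess(state, t)
        assert out[2, 0] == 0.0       # median -> 0
        assert out[4, 0] == 1.0       # (5-3)/2

    def test_constant_feature_divisor_one(self):
        t = _table_with_feature([5, 5, 5, 5])
        state = fit_preprocess(t)
        assert state.iqrs[0] == 0.0 and state.scales[0] == 1.0
        assert np.all(apply_preprocess(state, t) == 0.0)

    def test_masked_cell_ignored_in_fit_and_imputed_in_apply(self):
        t = _table_with_feature([1, 2, 3, 4, 5, 99], mask=[5])
        state = fit_preprocess(t)
        assert state.medians[0] == 3.0  # fitted on observed cells only
        out = apply_preprocess(state, t)
        assert out[5, 0] == 0.0         # imputed to median then scaled

    def test_fully_missing_feature_raises_with_name(self):
        t = _table_with_feature([1, 2, 3], mask=[0, 1, 2])
        with pytest.raises(ValidationError, match="f"):
            fit_preprocess(t)

    def test_scaling_invertible_for_observed_cells(self, clean_cohort):
        table, _, _ = clean_cohort
        state = fit_preprocess(table)
        out = apply_preprocess(state, table)
        back = out * state.scales + state.medians
        np.testing.assert_allclose(back, table.features.to_numpy(), rtol=1e-12)

    def test_no_test_set_leakage(self, small_cohort):
        table, _, _ = small_cohort
        train = table.subset(np.arange(0, 200))
        test = table.subset(np.arange(200, 250))
        state = fit_preprocess(train)
        perturbed = test.copy()
        perturbed.features.iloc[:, :] = perturbed.features.to_numpy() + 100.0
        state2 = fit_preprocess(train)  # refit: identical regardless of test
        np.testing.assert_array_equal(state.medians, state2.medians)
        # applying to perturbed test rows never mutates the state
        apply_preprocess(state, perturbed)
        np.testing.assert_array_equal(state.medians, state2.medians)


class TestAssembly:
    def test_block_widths(self, small_cohort):
        table, _, _ = small_cohort
        state = fit_preprocess(table)
        brain = apply_preprocess(state, table)
        cov, names = covariate_block(state, table)
        n_sites = len(state.site_levels)
        assert cov.shape[1] == 1 + 2 + n_sites == len(names)
        full = assemble_features(brain, cov, "brain_plus_covariates")
        assert full.shape[1] == 157 + 1 + 2 + n_sites
        assert assemble_features(brain, cov, "brain_only").shape[1] == 157
        assert assemble_features(brain, cov, "covariates_only").shape[1] == cov.shape[1]

    def test_onehot_rows_sum_to_one_for_seen_levels(self, small_cohort):
        table, _, _ = small_cohort
        state = fit_preprocess(table)
        cov, names = covariate_block(state, table)
        sex_cols = [i for i, n in enumerate(names) if n.startswith("sex=")]
        site_cols = [i for i, n in enumerate(names) if n.startswith("site=")]
        assert np.all(cov[:, sex_cols].sum(axis=1) == 1.0)
        assert np.all(cov[:, site_cols].sum(axis=1) == 1.0)

    def test_unseen_level_encodes_all_zero(self, small_cohort):
        table, _, _ = small_cohort
        train = table.subset(np.flatnonzero(table.site_id != "site00"))
        state = fit_preprocess(train)
        held_out = table.subset(np.flatnonzero(table.site_id == "site00"))
        cov, names = covariate_block(state, held_out)
        site_cols = [i for i, n in enumerate(names) if n.startswith("site=")]
        assert np.all(cov[:, site_cols].sum(axis=1) == 0.0)

    def test_residualized_regime_requires_residualizer(self, small_cohort):
        table, _, _ = small_cohort
        state = fit_preprocess(table)
        brain = apply_preprocess(state, table)
        cov, _ = covariate_block(state, table)
        with pytest.raises(ContractError):
            assemble_features(brain, cov, "residualized_brain")

    def test_schema_mismatch_detected(self, small_cohort):
        table, _, _ = small_cohort
        state = fit_preprocess(table)
        other = make_toy_table(n=5, p=3)
        with pytest.raises(SchemaError):
            apply_preprocess(state, other)
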