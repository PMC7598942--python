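"""Structural properties of the four fold-plan constructors."""

import numpy as np
import pytest

from sitelearn.errors import ValidationError
from sitelearn.folds import (
    FoldPlan,
    loso_folds,
    matched_size_folds,
    repeated_kfold,
    site_stratified_folds,
)

from conftest import make_toy_table


def _cell_counts(table, plan):
    """fold -> (site, dx) -> count."""
    out = []
    for _, te in plan.folds:
        d = {}
        for i in te:
            key = (table.site_id[i], table.diagnosis[i])
            d[key] = d.get(key, 0) + 1
        out.append(d)
    return out


class TestSiteStratified:
    def test_exact_divisibility_case(self):
        # one diagnosis per site keeps each (site x dx) cell at 50 subjects
        t = make_toy_table(n=100, n_sites=2, p=3)
        t.meta["diagnosis"] = [i % 2 for i in range(100)]  # == site index
        plan = site_stratified_folds(t, k=10, seed=0)
        assert sorted(plan.test_sizes()) == [10] * 10
        for _, te in plan.folds:
            per_site = [sum(t.site_id[i] == f"site{s}" for i in te) for s in (0, 1)]
            assert per_site == [5, 5]

    def test_small_site_spread_one_per_fold(self):
        t = make_toy_table(n=43, n_sites=1, p=3)
        # add a 3-subject second site (single diagnosis -> one cell of 3)
        t.meta.loc[40:, "site_id"] = "tiny"
        t.meta.loc[40:, "diagnosis"] = 1
        plan = site_stratified_folds(t, k=10, seed=1)
        counts = [sum(t.site_id[i] == "tiny" for i in te) for _, te in plan.folds]
        assert max(counts) == 1 and sum(counts) == 3

    def test_global_and_cell_balance(self, small_cohort):
        table, _, _ = small_cohort
        plan = site_stratified_folds(table, k=10, seed=5)
        plan.check_partition(table.n)
        sizes = plan.test_sizes()
        assert max(sizes) - min(sizes) <= 1
        cells = _cell_counts(table, plan)
        keys = {k for d in cells for k in d}
        for key in keys:
            per_fold = [d.get(key, 0) for d in cells]
            assert max(per_fold) - min(per_fold) <= 1

    def test_k_larger_than_n_rejected(self):
        t = make_toy_table(n=6, p=2)
        with pytest.raises(ValidationError):
            site_stratified_folds(t, k=10)

    def test_seed_determinism_and_variation(self, small_cohort):
        table, _, _ = small_cohort
        p1 = site_stratified_folds(table, k=10, seed=5)
        p2 = site_stratified_folds(table, k=10, seed=5)
        p3 = site_stratified_folds(table, k=10, seed=6)
        for (a, b), (c, d) in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(b, d)
        assert any(
            not np.array_equal(b, d) for (_, b), (_, d) in zip(p1.folds, p3.folds)
        )


class TestLoso:
    def test_one_fold_per_site(self, small_cohort):
        table, _, _ = small_cohort
        plan = loso_folds(table)
        assert plan.n_folds == len(np.unique(table.site_id))
        plan.check_partition(table.n)
        for (_, te), sites in zip(plan.folds, plan.fold_sites):
            assert len(set(table.site_id[te])) == 1 == len(sites)

    def test_single_site_rejected(self):
        t = make_toy_table(n=10, n_sites=1)
        with pytest.raises(ValidationError):
            loso_folds(t)

    def test_single_class_site_flagged(self):
        t = make_toy_table(n=20, n_sites=2)
        t.meta.loc[t.meta.site_id == "site1", "diagnosis"] = 1  # cases only
        plan = loso_folds(t)
        flags = dict(zip([s[0] for s in plan.fold_sites], plan.single_class_test))
        assert flags["site1"] is True and flags["site0"] is False


class TestMatchedSize:
    def test_size_multiset_matches_loso_exactly(self, small_cohort):
        table, _, _ = small_cohort
        lp = loso_folds(table)
        mp = matched_size_folds(table, lp, seed=2)
        assert sorted(mp.test_sizes()) == sorted(lp.test_sizes())
        mp.check_partition(table.n)
        # unlike LOSO, matched folds mix sites
        assert all(len(s) > 1 for s in mp.fold_sites)

    def test_two_equal_sites_reduce_to_halves(self):
        t = make_toy_table(n=40, n_sites=2)
        mp = matched_size_folds(t, loso_folds(t), seed=0)
        assert mp.test_sizes() == [20, 20]

    def test_determinism(self, small_cohort):
        table, _, _ = small_cohort
        lp = loso_folds(table)
        m1 = matched_size_folds(table, lp, seed=9)
        m2 = matched_size_folds(table, lp, seed=9)
        for (_, a), (_, b) in zip(m1.folds, m2.folds):
            np.testing.assert_array_equal(a, b)


class TestRepeatedKFold:
    def test_fold_sizes_and_counts(self):
        t = make_toy_table(n=50, n_sites=1)
        plans = repeated_kfold(t, k=5, repeats=10, seed=3)
        assert len(plans) == 10
        assert sum(p.n_folds for p in plans) == 50  # 50 (fold, repeat) pairs
        for p in plans:
            assert p.test_sizes() == [10] * 5
            p.check_partition(50)

    def test_repeats_differ(self):
        t = make_toy_table(n=24, n_sites=1)
        p = repeated_kfold(t, k=4, repeats=2, seed=0)
        a = np.concatenate([te for _, te in p[0].folds])
        b = np.concatenate([te for _, te in p[1].folds])
        assert not np.array_equal(a, b)

    def test_too_few_per_class_rejected(self):
        t = make_toy_table(n=8, n_sites=1)
        with pytest.raises(ValidationError, match="smaller k"):
            repeated_kfold(t, k=5, repeats=2, seed=0)


def test_plan_json_roundtrip(tmp_path, small_cohort):
    table, _, _ = small_cohort
    plan = site_stratified_folds(table, k=5, seed=4)
    path = tmp_path / "plan.json"
    plan.to_json(path, subject_ids=list(table.meta["subject_id"]))
    back = FoldPlan.from_json(path)
    assert back.scheme == plan.scheme
    for (a, b), (c, d) in zip(plan.folds, back.folds):
        np.testing.assert_array_equal(a, c)
        np.testing.assert_array_equal(b, d)
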