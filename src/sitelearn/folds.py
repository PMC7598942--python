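"""Fold plans for the four validation designs.

* ``site_stratified_folds`` — k folds with global sizes differing by at most
  one and, within every (site x diagnosis) cell, per-fold counts differing
  by at most one ("maximally homogeneous" splits).
* ``loso_folds`` — leave-one-site-out: each site once as the whole test set.
* ``matched_size_folds`` — site/diagnosis-stratified folds whose test-size
  multiset exactly equals the LOSO test-size multiset, isolating fold-size
  variance from between-site heterogeneity.
* ``repeated_kfold`` — diagnosis-stratified k-fold, repeated with
  independent derived seeds (single-site evaluation).

All assignments are randomized under a seed after a stable sort by
subject_id, so plans replay identically across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, ValidationError
from .table import SubjectTable
from ._seeds import derive_rng, derive_seed

__all__ = [
    "FoldPlan",
    "site_stratified_folds",
    "loso_folds",
    "matched_size_folds",
    "repeated_kfold",
]


@dataclass
class FoldPlan:
    """Ordered (train, test) index pairs plus scheme metadata.

    Indices are positions into the table the plan was built from.
    ``single_class_test`` flags folds whose test set contains one class
    only (AUC undefined there; evaluation skips them with a logged count).
    """

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int | None = None
    repeat: int = 0
    single_class_test: list[bool] = field(default_factory=list)
    fold_sites: list[list[str]] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def test_sizes(self) -> list[int]:
        return [len(te) for _, te in self.folds]

    def check_partition(self, n: int) -> None:
        """Assert the partition property: test sets tile 0..n-1 disjointly."""
        seen = np.concatenate([te for _, te in self.folds])
        if len(seen) != n or len(np.unique(seen)) != n:
            raise ValidationError("test folds do not partition the cohort")
        for tr, te in self.folds:
            if np.intersect1d(tr, te).size:
                raise ValidationError("train and test overlap in a fold")

    def to_json(self, path, subject_ids: list[str] | None = None) -> None:
        d = {
            "scheme": self.scheme,
            "seed": self.seed,
            "repeat": self.repeat,
            "folds": [
                {"train": tr.tolist(), "test": te.tolist()}
                for tr, te in self.folds
            ],
            "single_class_test": self.single_class_test,
            "fold_sites": self.fold_sites,
        }
        if subject_ids is not None:
            d["subject_ids"] = list(subject_ids)
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            scheme=d["scheme"],
            folds=[
                (np.asarray(f["train"], dtype=int), np.asarray(f["test"], dtype=int))
                for f in d["folds"]
            ],
            seed=d.get("seed"),
            repeat=d.get("repeat", 0),
            single_class_test=d.get("single_class_test", []),
            fold_sites=d.get("fold_sites", []),
        )


def _finish(plan_scheme, assign, table, seed=None, repeat=0) -> FoldPlan:
    """Build a FoldPlan from a per-subject fold assignment vector."""
    k = int(assign.max()) + 1
    n = len(assign)
    all_idx = np.arange(n)
    folds = []
    single = []
    sites = []
    dx = table.diagnosis
    for f in range(k):
        te = all_idx[assign == f]
        tr = all_idx[assign != f]
        folds.append((tr, te))
        single.append(len(np.unique(dx[te])) < 2)
        sites.append(sorted(pd.unique(table.site_id[te]).tolist()))
    return FoldPlan(plan_scheme, folds, seed=seed, repeat=repeat,
                    single_class_test=single, fold_sites=sites)


def _stable_order(table: SubjectTable) -> np.ndarray:
    return np.argsort(table.meta["subject_id"].to_numpy(), kind="stable")


def site_stratified_folds(table: SubjectTable, k: int = 10, seed: int = 0) -> FoldPlan:
    """Site- and diagnosis-stratified k folds of near-equal size.

    Greedy cell-wise dealing: each (site x diagnosis) cell spreads its
    members as evenly as possible over the k folds (counts differ by <= 1
    within the cell); remainder units go to the currently least-loaded
    folds, which keeps the global fold sizes within one of each other.
    """
    n = table.n
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds cohort size n={n}")
    rng = derive_rng(seed, "site_stratified", k)
    order = _stable_order(table)
    site = table.site_id
    dx = table.diagnosis
    loads = np.zeros(k, dtype=int)
    assign = np.full(n, -1, dtype=int)
    cells = sorted(
        {(site[i], dx[i]) for i in range(n)}, key=lambda c: (str(c[0]), int(c[1]))
    )
    for s, d in cells:
        members = order[(site[order] == s) & (dx[order] == d)]
        members = rng.permutation(members)
        m = len(members)
        base, rem = divmod(m, k)
        # remainder units to the least-loaded folds (random among ties)
        tie_break = rng.permutation(k)
        by_load = np.lexsort((tie_break, loads))
        extra_folds = by_load[:rem]
        counts = np.full(k, base, dtype=int)
        counts[extra_folds] += 1
        fold_order = rng.permutation(k)
        pos = 0
        for f in fold_order:
            c = counts[f]
            assign[members[pos:pos + c]] = f
            pos += c
        loads += counts
    if loads.max() - loads.min() > 1:  # invariant of the greedy rule
        raise AssertionError("global fold-size balance violated")
    return _finish("site_stratified_fixed", assign, table, seed=seed)


def loso_folds(table: SubjectTable) -> FoldPlan:
    """One fold per site; fold i's test set is exactly site i (deterministic)."""
    sites = sorted(pd.unique(table.site_id).tolist())
    if len(sites) < 2:
        raise ValidationError("leave-one-site-out requires at least 2 sites")
    assign = np.zeros(table.n, dtype=int)
    index = {s: f for f, s in enumerate(sites)}
    for i, s in enumerate(table.site_id):
        assign[i] = index[s]
    return _finish("loso", assign, table)


def matched_size_folds(
    table: SubjectTable, loso_plan: FoldPlan, seed: int = 0
) -> FoldPlan:
    """Stratified folds whose test sizes exactly match the LOSO sizes.

    Subjects are dealt cell-by-cell (site first, diagnosis second, seeded
    shuffle within) to the fold with the largest remaining share of its
    size target, so every fold mixes sites while the test-size multiset
    equals the LOSO multiset exactly.
    """
    if sum(loso_plan.test_sizes()) != table.n:
        raise ContractError("loso plan was not derived from this table")
    targets = np.asarray(loso_plan.test_sizes(), dtype=int)
    k = len(targets)
    rng = derive_rng(seed, "matched_size", k)
    order = _stable_order(table)
    site = table.site_id
    dx = table.diagnosis
    remaining = targets.astype(float).copy()
    assign = np.full(table.n, -1, dtype=int)
    cells = sorted(
        {(site[i], dx[i]) for i in range(table.n)},
        key=lambda c: (str(c[0]), int(c[1])),
    )
    tie = rng.random(k) * 1e-9
    for s, d in cells:
        members = order[(site[order] == s) & (dx[order] == d)]
        members = rng.permutation(members)
        for i in members:
            share = remaining / targets + tie
            f = int(np.argmax(share))
            assign[i] = f
            remaining[f] -= 1.0
    if not np.all(remaining == 0):
        raise AssertionError("size targets not met exactly")
    return _finish("site_stratified_matched", assign, table, seed=seed)


def repeated_kfold(
    table: SubjectTable, k: int = 5, repeats: int = 10, seed: int = 0
) -> list[FoldPlan]:
    """Diagnosis-stratified k-fold, repeated with independent derived seeds."""
    dx = table.diagnosis
    n_case = int((dx == 1).sum())
    n_ctrl = int((dx == 0).sum())
    if min(n_case, n_ctrl) < k:
        raise ValidationError(
            f"fewer than k={k} subjects in a class (cases={n_case}, "
            f"controls={n_ctrl}); use a smaller k"
        )
    plans = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=derive_seed(seed, "repeat", r)
        )
        assign = np.full(table.n, -1, dtype=int)
        for f, (_, te) in enumerate(skf.split(np.zeros(table.n), dx)):
            assign[te] = f
        plans.append(_finish("single_site_repeated", assign, table, seed=seed, repeat=r))
    return plans
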