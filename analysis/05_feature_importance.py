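"""Permutation feature importance with per-fold FDR and consistency.

Runs the random-forest response-permutation importance on residualized
brain features, per fold, with Benjamini-Hochberg selection at q=0.05
inside each fold and the strict >50%-of-folds consistency rule across
folds.  Two panels are run:

* the full 157-feature panel with 10 injected features — at B=200 the
  per-feature p-value floor (1/201) sits above the BH entry threshold for
  157 tests, so per-fold selection is empty by construction and no
  feature can be consistent;
* a 30-feature panel where the same machinery recovers every injected
  feature.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from sitelearn.cohort import CohortConfig, generate_cohort
from sitelearn.folds import site_stratified_folds
from sitelearn.importance import run_fold_importance
from sitelearn.models import ModelSpec
from sitelearn.pipeline import _fold_design

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "importance"


def run_panel(n_features, n_informative, d, seed, folds=10, B=200):
    cfg = CohortConfig(n_sites=2, site_size_range=(50, 50), case_fraction=0.5,
                       n_features=n_features,
                       diagnosis_effect=(n_informative, d),
                       medication_effect=(0, 0.0), site_offset_sd=0.0,
                       site_scale_sd=0.0, missing_rate=0.0,
                       heavy_missing_fraction=0.0, seed=seed)
    table, gt = generate_cohort(cfg)
    plan = site_stratified_folds(table, k=folds, seed=seed)
    mats = []
    for tr_idx, _ in plan.folds:
        train = table.subset(tr_idx)
        X_tr, _ = _fold_design(train, train, "residualized_brain")
        mats.append((X_tr, table.diagnosis[tr_idx]))
    spec = ModelSpec("rfc", params={"n_estimators": 50})
    result = run_fold_importance(mats, table.feature_names, spec, B=B,
                                 seed=seed)
    informative = np.zeros(n_features, dtype=bool)
    informative[gt.dx_affected] = True
    return result, informative


def main(seed=1):
    OUT.mkdir(parents=True, exist_ok=True)
    res_full, inf_full = run_panel(157, 10, 1.0, seed, folds=4)
    res_full.summary().to_csv(OUT / "importance_157.tsv", sep="\t", index=False)
    print(f"157-feature panel: {res_full.consistent.sum()} consistent features "
          f"({res_full.consistent[inf_full].sum()} of 10 injected) — at "
          "B=200 the p-floor 1/201 exceeds the BH entry threshold "
          "0.05/157, so selection is structurally empty")

    res_small, inf_small = run_panel(30, 5, 2.0, seed, folds=4)
    res_small.summary().to_csv(OUT / "importance_30.tsv", sep="\t", index=False)
    print(f"30-feature panel: {res_small.consistent.sum()} consistent features "
          f"({res_small.consistent[inf_small].sum()} of 5 injected)")


if __name__ == "__main__":
    main()
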