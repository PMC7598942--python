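"""Within-site classification and the site-size vs performance correlation.

Runs repeated 5-fold CV (3 repeats here) with the random forest inside
each site separately, then correlates each site's sample size with its
mean fold AUC (Spearman).  Writes the per-site table and a scatter plot.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from sitelearn._seeds import derive_seed
from sitelearn.cohort import CohortConfig, generate_cohort
from sitelearn.folds import repeated_kfold
from sitelearn.models import ModelSpec
from sitelearn.pipeline import RunConfig, evaluate_model_on_plan
from sitelearn.preprocess import exclude_high_missingness
from sitelearn.stats import site_size_performance_correlation

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "single_site"


def main(seed=1):
    cfg = CohortConfig(n_sites=14, site_size_range=(40, 220),
                       case_fraction=0.5, diagnosis_effect=(20, 0.5),
                       medication_effect=(0, 0.0), seed=seed)
    table, _ = generate_cohort(cfg)
    table, _ = exclude_high_missingness(table)
    spec = ModelSpec("rfc", params={"n_estimators": 50})
    rows = []
    for s in np.unique(table.site_id):
        sub = table.subset(np.flatnonzero(table.site_id == s))
        plans = repeated_kfold(sub, k=5, repeats=3,
                               seed=derive_seed(seed, "folds", s))
        config = RunConfig(cv_scheme="single_site_repeated", model_specs=[spec],
                           tune=False, seed=derive_seed(seed, "run", s))
        rep = evaluate_model_on_plan(sub, sub.diagnosis, plans, spec, config,
                                     "diagnosis")
        rows.append({"site": s, "n": sub.n, "mean_fold_auc": rep.mean_fold_auc,
                     "sd_fold_auc": rep.sd_fold_auc})
    out = pd.DataFrame(rows)
    rho, p = site_size_performance_correlation(out["mean_fold_auc"], out["n"])
    OUT.mkdir(parents=True, exist_ok=True)
    out.to_csv(OUT / "per_site_auc.tsv", sep="\t", index=False)
    print(out.round(3).to_string(index=False))
    print(f"\nSpearman site size vs AUC: rho = {rho:.2f}, p = {p:.3f}")
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(out["n"], out["mean_fold_auc"])
        ax.axhline(0.5, ls="--", c="grey")
        ax.set_xlabel("site sample size")
        ax.set_ylabel("mean fold AUC (5-fold x 3 repeats)")
        ax.set_title(f"Spearman rho = {rho:.2f}, p = {p:.3f}")
        fig.tight_layout()
        fig.savefig(OUT / "site_size_vs_auc.png", dpi=120)
        print(f"wrote {OUT / 'site_size_vs_auc.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the scatter plot")


if __name__ == "__main__":
    main()
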