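"""Permutation feature importance for the random forest, with per-fold FDR.

Observed importance is the forest's impurity-based importance on the true
labels.  The null distribution is response-permutation: the labels are
permuted B times (the same derived permutations for every feature) and the
forest refit; each refit yields a null importance for every feature at
once.  Per-feature p = (1 + #null >= observed) / (B + 1), so the smallest
attainable p is exactly 1/(B+1) and zero p-values never occur.  Selection
is Benjamini-Hochberg per fold at q, and a feature counts as consistent
when it is selected in strictly more than half of the evaluated folds.

Importance runs on residualized brain features only — covariate columns
never enter this module (importance would otherwise be dominated by
site/age indicators rather than anatomy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .models import ModelSpec, fit_model
from ._seeds import derive_rng, derive_seed

__all__ = [
    "permutation_importance",
    "fdr_bh",
    "consistency_filter",
    "ImportanceTable",
    "run_fold_importance",
]


def permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    B: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (observed importance, permutation p-value).

    Requires a random-forest spec and B >= 50 (below that the p-value
    resolution is too coarse for FDR at 0.05).
    """
    if spec.family != "rfc":
        raise ContractError("permutation importance is defined for the RFC only")
    if B < 50:
        raise ValidationError(f"B={B} too small; need B >= 50 for usable p-values")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)

    observed = fit_model(spec, X, y, tune=False).estimator.feature_importances_
    rng = derive_rng(seed, "importance_null")
    exceed = np.zeros(X.shape[1], dtype=int)
    for b in range(B):
        yb = rng.permutation(y)
        imp_b = fit_model(spec, X, yb, tune=False).estimator.feature_importances_
        exceed += imp_b >= observed
    p = (1.0 + exceed) / (B + 1.0)
    return np.asarray(observed, dtype=float), p


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (selected flags, adjusted q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # enforce monotonicity
    adj = np.minimum(adj, 1.0)
    qvals = np.empty(m)
    qvals[order] = adj
    selected = qvals <= q
    return selected, qvals


def consistency_filter(selections: np.ndarray, n_folds: int | None = None
                       ) -> np.ndarray:
    """Features selected in strictly more than half of the folds.

    ``selections`` is (n_folds, n_features) boolean.
    """
    sel = np.asarray(selections, dtype=bool)
    if sel.ndim != 2 or sel.shape[0] < 2:
        raise ValidationError("need per-fold selections for at least 2 folds")
    k = n_folds if n_folds is not None else sel.shape[0]
    counts = sel.sum(axis=0)
    return counts > k / 2.0


@dataclass
class ImportanceTable:
    """Per-fold importance results plus the cross-fold consistency summary."""

    feature_names: list[str]
    per_fold: pd.DataFrame     # fold, feature, importance, p, q, selected
    selected_counts: np.ndarray
    consistent: np.ndarray     # bool per feature
    n_folds: int
    B: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "folds_selected": self.selected_counts,
                "consistent": self.consistent,
            }
        )


def run_fold_importance(
    fold_matrices: list[tuple[np.ndarray, np.ndarray]],
    feature_names: list[str],
    spec: ModelSpec,
    B: int = 200,
    q: float = 0.05,
    seed: int = 0,
) -> ImportanceTable:
    """Importance + BH selection per fold, then the >50% consistency filter.

    ``fold_matrices`` are (train X, train y) pairs of residualized brain
    features; any attempt to pass wider matrices than the feature-name list
    is rejected, which is how the no-covariates contract is enforced.
    """
    p_feat = len(feature_names)
    rows = []
    selections = []
    for f, (X, y) in enumerate(fold_matrices):
        if X.shape[1] != p_feat:
            raise ContractError(
                f"fold {f}: matrix has {X.shape[1]} columns but "
                f"{p_feat} brain features were declared — covariate "
                "columns must not reach the importance module"
            )
        obs, pvals = permutation_importance(X, y, spec, B=B,
                                            seed=derive_seed(seed, "fold", f))
        sel, qvals = fdr_bh(pvals, q=q)
        selections.append(sel)
        rows.append(pd.DataFrame({
            "fold": f,
            "feature": feature_names,
            "importance": obs,
            "p": pvals,
            "q": qvals,
            "selected": sel,
        }))
    selections = np.asarray(selections)
    consistent = consistency_filter(selections)
    return ImportanceTable(
        feature_names=list(feature_names),
        per_fold=pd.concat(rows, ignore_index=True),
        selected_counts=selections.sum(axis=0),
        consistent=consistent,
        n_folds=len(fold_matrices),
        B=B,
    )
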