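"""Train-fit covariate residualization (confound control).

Each brain feature is regressed on an intercept, age, sex indicators minus
a reference level and site indicators minus a reference level, by ordinary
least squares on the *training* rows only; the stored coefficients are then
subtracted from both training and test rows.  Under leave-one-site-out the
held-out site's indicator does not exist in the design and the site behaves
as the reference level (its contribution is zero).

Solver: thin QR of the design matrix; rank deficiency (for example a
duplicated covariate column, or a site indicator collinear with the
intercept) raises an error naming the offending columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .errors import ContractError, SchemaError, ValidationError

__all__ = ["Residualizer", "fit_residualizer", "apply_residualizer"]


@dataclass
class Residualizer:
    """Per-feature OLS coefficients on the covariate design."""

    columns: list[str]       # design column names, intercept first
    sex_levels: list[str]    # full inventory; first entry is the reference
    site_levels: list[str]
    coef: np.ndarray         # (n_design_columns, n_features)
    n_train: int

    def export_tsv(self, path, feature_names: list[str]) -> None:
        df = pd.DataFrame(self.coef.T, index=feature_names, columns=self.columns)
        df.to_csv(path, sep="\t", index_label="feature")


def _design(
    covariates: pd.DataFrame,
    sex_levels: list[str],
    site_levels: list[str],
) -> tuple[np.ndarray, list[str]]:
    n = len(covariates)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append(covariates["age"].to_numpy(dtype=float))
    names.append("age")
    sex = covariates["sex"].to_numpy()
    for lv in sex_levels[1:]:  # reference level dropped
        cols.append((sex == lv).astype(float))
        names.append(f"sex={lv}")
    site = covariates["site_id"].to_numpy()
    for lv in site_levels[1:]:
        cols.append((site == lv).astype(float))
        names.append(f"site={lv}")
    return np.column_stack(cols), names


def fit_residualizer(features: np.ndarray, covariates: pd.DataFrame) -> Residualizer:
    """OLS fit of every feature on [1 | age | sex | site] (train rows only).

    ``covariates`` needs columns age, sex, site_id.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    for col in ("age", "sex", "site_id"):
        if col not in covariates.columns:
            raise SchemaError(f"covariate column missing: {col!r}")
    X = np.asarray(features, dtype=float)
    sex_levels = sorted(pd.unique(covariates["sex"].dropna()).tolist())
    site_levels = sorted(pd.unique(covariates["site_id"]).tolist())
    D, names = _design(covariates, sex_levels, site_levels)
    if D.shape[0] < D.shape[1] + 1:
        raise ValidationError(
            f"need at least {D.shape[1] + 1} training rows for {D.shape[1]} "
            f"design columns, got {D.shape[0]}"
        )
    Q, R = np.linalg.qr(D)
    diag = np.abs(np.diag(R))
    tol = max(D.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = diag < tol
    if bad.any():
        offenders = [names[j] for j in np.flatnonzero(bad)]
        raise ValidationError(f"rank-deficient covariate design; columns: {offenders}")
    coef = solve_triangular(R, Q.T @ X)
    return Residualizer(
        columns=names,
        sex_levels=sex_levels,
        site_levels=site_levels,
        coef=coef,
        n_train=D.shape[0],
    )


def apply_residualizer(
    res: Residualizer, features: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """features - design @ coef; unseen site/sex levels contribute zero."""
    for col in ("age", "sex", "site_id"):
        if col not in covariates.columns:
            raise SchemaError(f"covariate column missing: {col!r}")
    X = np.asarray(features, dtype=float)
    if X.shape[1] != res.coef.shape[1]:
        raise ContractError(
            f"feature width {X.shape[1]} does not match fitted width "
            f"{res.coef.shape[1]}"
        )
    D, _ = _design(covariates, res.sex_levels, res.site_levels)
    return X - D @ res.coef
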