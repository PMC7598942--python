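"""In-fold preprocessing: exclusion, train-median imputation, robust scaling.

Order of operations mirrors the analysis this package implements:

1. subjects with strictly more than 10% missing feature cells are excluded
   once, globally, before any cross-validation split;
2. per fold, feature medians and interquartile ranges are fitted on the
   observed training cells only;
3. missing cells are imputed with the train median, then every feature is
   centered at median zero and scaled by its train IQR (linear-interpolation
   quartiles; IQR of 0 falls back to a divisor of 1);
4. covariates (age, one-hot sex, one-hot site) are concatenated according
   to the requested feature regime.  One-hot blocks keep all levels; an
   unseen level encodes as all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, SchemaError, ValidationError
from .table import SubjectTable

__all__ = [
    "PreprocessState",
    "exclude_high_missingness",
    "fit_preprocess",
    "apply_preprocess",
    "covariate_block",
    "assemble_features",
    "FEATURE_REGIMES",
]

FEATURE_REGIMES = (
    "brain_plus_covariates",
    "brain_only",
    "covariates_only",
    "residualized_brain",
)


@dataclass
class PreprocessState:
    """Train-fitted statistics; applying it never refits anything."""

    feature_names: list[str]
    medians: np.ndarray
    iqrs: np.ndarray
    scales: np.ndarray  # iqr, or 1 where iqr == 0
    age_median: float
    age_iqr: float
    sex_levels: list[str]
    site_levels: list[str]


def exclude_high_missingness(
    table: SubjectTable, threshold: float = 0.10
) -> tuple[SubjectTable, pd.DataFrame]:
    """Drop subjects with strictly more than ``threshold`` missing cells.

    Returns the filtered table and an exclusion report
    (subject_id, missing_fraction, reason).
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    frac = table.missing_mask.mean(axis=1)
    drop = frac > threshold
    report = pd.DataFrame(
        {
            "subject_id": table.meta.loc[drop, "subject_id"].to_numpy(),
            "missing_fraction": frac[drop],
            "reason": f"missing fraction > {threshold:g}",
        }
    )
    if drop.all():
        raise ValidationError("all subjects exceeded the missingness threshold")
    kept = table.subset(np.flatnonzero(~drop))
    return kept, report


def fit_preprocess(train: SubjectTable) -> PreprocessState:
    """Fit medians/IQRs on observed train cells; inventory categorical levels."""
    if train.n == 0:
        raise ValidationError("training table is empty")
    X = train.features.to_numpy(dtype=float)
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [train.feature_names[i] for i in np.flatnonzero(all_missing)]
        raise ValidationError(f"features fully missing in train: {bad}")
    medians = np.nanmedian(X, axis=0)
    q1 = np.nanpercentile(X, 25, axis=0)  # linear interpolation
    q3 = np.nanpercentile(X, 75, axis=0)
    iqrs = q3 - q1
    scales = np.where(iqrs > 0, iqrs, 1.0)

    age = train.meta["age"].to_numpy(dtype=float)
    age_median = float(np.nanmedian(age))
    age_q1, age_q3 = np.nanpercentile(age, [25, 75])
    age_iqr = float(age_q3 - age_q1)

    sex_levels = sorted(pd.unique(train.meta["sex"].dropna()).tolist())
    site_levels = sorted(pd.unique(train.meta["site_id"]).tolist())
    return PreprocessState(
        feature_names=train.feature_names,
        medians=medians,
        iqrs=iqrs,
        scales=scales,
        age_median=age_median,
        age_iqr=age_iqr if age_iqr > 0 else 1.0,
        sex_levels=sex_levels,
        site_levels=site_levels,
    )


def apply_preprocess(state: PreprocessState, table: SubjectTable) -> np.ndarray:
    """Impute masked cells with train medians, then robust-scale.

    Returns the scaled brain-feature block (n, n_features).
    """
    if table.feature_names != state.feature_names:
        diff = set(table.feature_names) ^ set(state.feature_names)
        raise SchemaError(f"feature names differ from fitted state: {sorted(diff)[:10]}")
    X = table.features.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    X[miss] = np.broadcast_to(state.medians, X.shape)[miss]
    return (X - state.medians) / state.scales


def _onehot(values: np.ndarray, levels: list[str]) -> np.ndarray:
    out = np.zeros((len(values), len(levels)))
    index = {lv: j for j, lv in enumerate(levels)}
    for i, v in enumerate(values):
        j = index.get(v)
        if j is not None:  # unseen level -> all-zero row
            out[i, j] = 1.0
    return out


def covariate_block(
    state: PreprocessState, table: SubjectTable
) -> tuple[np.ndarray, list[str]]:
    """[scaled age | one-hot sex | one-hot site] with column names."""
    age = table.meta["age"].to_numpy(dtype=float)
    age_scaled = (age - state.age_median) / state.age_iqr
    sex = _onehot(table.meta["sex"].to_numpy(), state.sex_levels)
    site = _onehot(table.meta["site_id"].to_numpy(), state.site_levels)
    block = np.column_stack([age_scaled, sex, site])
    names = (
        ["age"]
        + [f"sex={lv}" for lv in state.sex_levels]
        + [f"site={lv}" for lv in state.site_levels]
    )
    return block, names


def assemble_features(
    brain: np.ndarray,
    covariates: np.ndarray,
    regime: str,
    residualized: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate blocks according to the feature regime.

    ``residualized_brain`` requires the residualized block computed by the
    confound-control module (coefficients fitted on training rows only).
    """
    if regime not in FEATURE_REGIMES:
        raise ValidationError(f"unknown regime {regime!r}; one of {FEATURE_REGIMES}")
    if regime == "brain_plus_covariates":
        return np.column_stack([brain, covariates])
    if regime == "brain_only":
        return np.asarray(brain)
    if regime == "covariates_only":
        return np.asarray(covariates)
    if residualized is None:
        raise ContractError(
            "regime 'residualized_brain' requires a fitted residualizer output"
        )
    return np.asarray(residualized)
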