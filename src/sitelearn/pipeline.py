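"""End-to-end orchestration: configuration, per-fold evaluation, reports.

``run_pipeline`` ties the stages together: global missingness exclusion,
fold-plan construction for the requested validation scheme, in-fold
preprocessing and feature-regime assembly (including train-fit covariate
residualization), model fitting and scoring, and rank-based AUC inference
with Bonferroni control.  All randomness expands deterministically from
``RunConfig.seed`` via the documented seed-splitting rule, so identical
configs yield bit-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .folds import (
    FoldPlan,
    loso_folds,
    matched_size_folds,
    repeated_kfold,
    site_stratified_folds,
)
from .models import ModelSpec, canonical_specs, fit_model, predict_scores, score_threshold
from .preprocess import (
    FEATURE_REGIMES,
    apply_preprocess,
    assemble_features,
    covariate_block,
    exclude_high_missingness,
    fit_preprocess,
)
from .residualize import apply_residualizer, fit_residualizer
from .stats import auc_rank, bonferroni, mwu_auc_inference, secondary_metrics
from .subgroups import ContrastSpec
from .table import SubjectTable
from ._seeds import derive_seed

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "evaluate_model_on_plan"]

log = logging.getLogger("sitelearn")

CV_SCHEMES = ("site_stratified_fixed", "loso", "site_stratified_matched",
              "single_site_repeated")


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    cv_scheme: str = "site_stratified_fixed"
    n_folds: int = 10
    n_repeats: int = 10
    model_specs: list[ModelSpec] = field(default_factory=lambda: canonical_specs())
    feature_regime: str = "brain_plus_covariates"
    subgroup_contrast: ContrastSpec | None = None
    alpha: float = 0.05
    n_comparisons: int = 30
    missing_threshold: float = 0.10
    tune: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.cv_scheme not in CV_SCHEMES:
            raise ValidationError(f"unknown cv_scheme {self.cv_scheme!r}")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.feature_regime not in FEATURE_REGIMES:
            raise ValidationError(f"unknown regime {self.feature_regime!r}")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    # -- config file round trip -----------------------------------------
    def to_dict(self) -> dict:
        d = {
            "cv_scheme": self.cv_scheme,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "model_specs": [
                {"family": s.family, "pca": s.pca, "tuning_grid": s.tuning_grid,
                 "inner_cv_folds": s.inner_cv_folds, "seed": s.seed,
                 "params": s.params}
                for s in self.model_specs
            ],
            "feature_regime": self.feature_regime,
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "missing_threshold": self.missing_threshold,
            "tune": self.tune,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        specs = [ModelSpec(**s) for s in d.pop("model_specs", [])]
        if not specs:
            specs = canonical_specs()
        return cls(model_specs=specs, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class AnalysisReport:
    """Fold-wise and pooled performance for one (model, scheme, contrast)."""

    model_id: str
    scheme: str
    regime: str
    contrast: str
    n_subjects: int
    n_cases: int
    n_controls: int
    fold_auc: list[float]
    fold_balanced_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    mean_fold_auc: float
    sd_fold_auc: float
    pooled_auc: float
    u_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    alpha: float
    n_comparisons: int
    significant_corrected: bool
    n_skipped_single_class_folds: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reports_to_frame(reports: list[AnalysisReport]) -> pd.DataFrame:
    """Flat summary table: one row per (model x scheme x contrast)."""
    rows = []
    for r in reports:
        rows.append({
            "model": r.model_id, "scheme": r.scheme, "regime": r.regime,
            "contrast": r.contrast, "n": r.n_subjects,
            "pooled_auc": r.pooled_auc, "mean_fold_auc": r.mean_fold_auc,
            "sd_fold_auc": r.sd_fold_auc, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "p": r.p_value,
            "significant_corrected": r.significant_corrected,
            "skipped_folds": r.n_skipped_single_class_folds,
        })
    return pd.DataFrame(rows)


def build_fold_plans(table: SubjectTable, config: RunConfig) -> list[FoldPlan]:
    seed = derive_seed(config.seed, "folds", config.cv_scheme)
    if config.cv_scheme == "site_stratified_fixed":
        return [site_stratified_folds(table, k=config.n_folds, seed=seed)]
    if config.cv_scheme == "loso":
        return [loso_folds(table)]
    if config.cv_scheme == "site_stratified_matched":
        return [matched_size_folds(table, loso_folds(table), seed=seed)]
    return repeated_kfold(table, k=config.n_folds, repeats=config.n_repeats,
                          seed=seed)


def _fold_design(
    train: SubjectTable, test: SubjectTable, regime: str
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test design matrices for one fold under one feature regime.

    All statistics (medians, IQRs, categorical inventories, residualizer
    coefficients) are fitted on the training rows only.
    """
    state = fit_preprocess(train)
    n_imp = int(train.missing_mask.sum() + test.missing_mask.sum())
    if n_imp:
        log.debug("fold: imputing %d missing cells with train medians", n_imp)
    brain_tr = apply_preprocess(state, train)
    brain_te = apply_preprocess(state, test)
    cov_tr, _ = covariate_block(state, train)
    cov_te, _ = covariate_block(state, test)
    res_tr = res_te = None
    if regime == "residualized_brain":
        covdf_tr = train.meta[["age", "sex", "site_id"]]
        covdf_te = test.meta[["age", "sex", "site_id"]]
        res = fit_residualizer(brain_tr, covdf_tr)
        res_tr = apply_residualizer(res, brain_tr, covdf_tr)
        res_te = apply_residualizer(res, brain_te, covdf_te)
    X_tr = assemble_features(brain_tr, cov_tr, regime, residualized=res_tr)
    X_te = assemble_features(brain_te, cov_te, regime, residualized=res_te)
    return X_tr, X_te


def evaluate_model_on_plan(
    table: SubjectTable,
    y: np.ndarray,
    plans: list[FoldPlan],
    spec: ModelSpec,
    config: RunConfig,
    contrast_name: str = "diagnosis",
) -> AnalysisReport:
    """Fit/score one model spec across all folds of all plans (repeats)."""
    regime = config.feature_regime
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    fold_auc, fold_bacc, fold_sens, fold_spec = [], [], [], []
    skipped = 0
    for plan in plans:
        plan.check_partition(table.n)
        for f, (tr_idx, te_idx) in enumerate(plan.folds):
            train = table.subset(tr_idx)
            test = table.subset(te_idx)
            y_tr, y_te = y[tr_idx], y[te_idx]
            X_tr, X_te = _fold_design(train, test, regime)
            fold_seed = derive_seed(config.seed, "fit", spec.spec_id,
                                    plan.repeat, f)
            fitted = fit_model(
                dataclasses.replace(spec, seed=fold_seed), X_tr, y_tr,
                tune=config.tune,
            )
            s_te = predict_scores(fitted, X_te)
            pooled_scores.append(s_te)
            pooled_labels.append(y_te)
            if len(np.unique(y_te)) < 2:
                skipped += 1
                log.warning("fold %d (%s, repeat %d): single-class test set; "
                            "AUC skipped", f, plan.scheme, plan.repeat)
                continue
            fold_auc.append(auc_rank(s_te, y_te))
            bacc, sens, spc = secondary_metrics(
                s_te, y_te, threshold=score_threshold(fitted.score_kind))
            fold_bacc.append(bacc)
            fold_sens.append(sens)
            fold_spec.append(spc)
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    pooled = auc_rank(scores, labels)
    u, p, (lo, hi) = mwu_auc_inference(scores, labels, alpha=config.alpha)
    sig = bool(bonferroni([p], config.alpha, config.n_comparisons)[0])
    return AnalysisReport(
        model_id=spec.spec_id,
        scheme=plans[0].scheme,
        regime=regime,
        contrast=contrast_name,
        n_subjects=table.n,
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        fold_auc=[float(v) for v in fold_auc],
        fold_balanced_accuracy=[float(v) for v in fold_bacc],
        fold_sensitivity=[float(v) for v in fold_sens],
        fold_specificity=[float(v) for v in fold_spec],
        mean_fold_auc=float(np.mean(fold_auc)) if fold_auc else float("nan"),
        sd_fold_auc=float(np.std(fold_auc, ddof=1)) if len(fold_auc) > 1 else float("nan"),
        pooled_auc=float(pooled),
        u_statistic=float(u),
        p_value=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=config.alpha,
        n_comparisons=config.n_comparisons,
        significant_corrected=sig,
        n_skipped_single_class_folds=skipped,
        seed=config.seed,
    )


def run_pipeline(config: RunConfig, table: SubjectTable) -> list[AnalysisReport]:
    """One report per model spec for the configured scheme/regime/contrast."""
    config.validate()
    table.validate()
    table, excluded = exclude_high_missingness(table, config.missing_threshold)
    log.info("excluded %d subjects for >%.0f%% missingness",
             len(excluded), 100 * config.missing_threshold)
    if config.subgroup_contrast is not None:
        table, y = config.subgroup_contrast.apply(table)
        contrast_name = config.subgroup_contrast.name
    else:
        y = table.diagnosis
        contrast_name = "diagnosis"
    plans = build_fold_plans(table, config)
    log.info("scheme %s: %d plan(s), fold sizes %s", config.cv_scheme,
             len(plans), plans[0].test_sizes())
    reports = []
    for spec in config.model_specs:
        reports.append(
            evaluate_model_on_plan(table, y, plans, spec, config,
                                   contrast_name=contrast_name)
        )
        log.info("model %s: pooled AUC %.3f", spec.spec_id, reports[-1].pooled_auc)
    return reports
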