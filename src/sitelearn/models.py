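"""Classifier zoo behind a single train/predict contract.

Ten canonical configurations (linear/RBF SVM with and without PCA, L1/L2
logistic regression, PCA + logistic regression, linear-kernel Gaussian
process, random forest, XGBoost) plus a fully connected neural network with
hidden layers (60, 40, 20).  Optional PCA retains the minimal number of
components explaining 90% of the training variance.  SVM, logistic
regression and XGBoost are tuned by nested (inner) stratified CV on AUC;
the forest and the Gaussian process use fixed recommendation-level
settings.  All stochastic components are seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import DotProduct
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import ContractError, ValidationError
from ._seeds import derive_seed

__all__ = ["ModelSpec", "CANONICAL_SPECS", "FittedModel", "fit_model", "predict_scores"]

FAMILIES = (
    "svm_linear", "svm_rbf", "logreg_l1", "logreg_l2",
    "gpc_linear", "rfc", "xgb", "nn",
)

#: families whose hyperparameters are tuned by inner CV
TUNED_FAMILIES = ("svm_linear", "svm_rbf", "logreg_l1", "logreg_l2", "xgb")

#: families that may be combined with PCA reduction
PCA_FAMILIES = ("svm_linear", "svm_rbf", "logreg_l1", "logreg_l2")


@dataclass
class ModelSpec:
    """One classifier configuration.

    ``params`` overrides fixed settings (e.g. ``n_estimators`` for the
    forest); ``tuning_grid`` overrides the default grid for tuned families.
    """

    family: str
    pca: bool = False
    tuning_grid: dict[str, list] | None = None
    inner_cv_folds: int = 5
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.pca and self.family not in PCA_FAMILIES:
            raise ValidationError(f"PCA not supported for family {self.family!r}")

    @property
    def spec_id(self) -> str:
        return ("pca+" if self.pca else "") + self.family

    @property
    def tuned(self) -> bool:
        return self.family in TUNED_FAMILIES


def canonical_specs(seed: int = 0, rfc_trees: int = 200) -> list[ModelSpec]:
    """The ten multi-site configurations plus the neural network."""
    return [
        ModelSpec("svm_linear", seed=seed),
        ModelSpec("svm_linear", pca=True, seed=seed),
        ModelSpec("svm_rbf", seed=seed),
        ModelSpec("svm_rbf", pca=True, seed=seed),
        ModelSpec("logreg_l1", seed=seed),
        ModelSpec("logreg_l2", seed=seed),
        ModelSpec("logreg_l2", pca=True, seed=seed),
        ModelSpec("gpc_linear", seed=seed),
        ModelSpec("rfc", seed=seed, params={"n_estimators": rfc_trees}),
        ModelSpec("xgb", seed=seed),
        ModelSpec("nn", seed=seed),
    ]


CANONICAL_SPECS = canonical_specs()


@dataclass
class FittedModel:
    """A trained predictor plus how to read its scores."""

    spec: ModelSpec
    estimator: Any
    n_features_in: int
    score_kind: str  # "margin" (decision_function) or "probability"
    best_params: dict[str, Any] | None = None


def _base_estimator(spec: ModelSpec, seed: int, X: np.ndarray):
    p = spec.params
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=p.get("C", 1.0), random_state=seed), "margin"
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "scale"),
                   random_state=seed), "margin"
    if spec.family == "logreg_l1":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                  C=p.get("C", 1.0), max_iter=2000,
                                  random_state=seed), "probability"
    if spec.family == "logreg_l2":
        return LogisticRegression(l1_ratio=0.0, solver="lbfgs",
                                  C=p.get("C", 1.0), max_iter=2000,
                                  random_state=seed), "probability"
    if spec.family == "gpc_linear":
        return GaussianProcessClassifier(kernel=DotProduct(sigma_0=1.0),
                                         random_state=seed), "probability"
    if spec.family == "rfc":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 200),
            max_features=p.get("max_features", "sqrt"),
            random_state=seed, n_jobs=1,
        ), "probability"
    if spec.family == "xgb":
        return XGBClassifier(
            n_estimators=p.get("n_estimators", 200),
            max_depth=p.get("max_depth", 4),
            learning_rate=p.get("learning_rate", 0.1),
            random_state=seed, n_jobs=1, verbosity=0,
            eval_metric="logloss", tree_method="hist",
        ), "probability"
    if spec.family == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(60, 40, 20),
            early_stopping=True, validation_fraction=0.1,
            max_iter=p.get("max_iter", 300), random_state=seed,
        ), "probability"
    raise ValidationError(f"unknown family {spec.family!r}")


def _default_grid(spec: ModelSpec, X: np.ndarray) -> dict[str, list]:
    prefix = "clf__" if spec.pca else ""
    if spec.family in ("svm_linear",):
        return {prefix + "C": [0.01, 0.1, 1.0, 10.0]}
    if spec.family == "svm_rbf":
        var = float(X.var())
        gamma_scale = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        return {
            prefix + "C": [0.01, 0.1, 1.0, 10.0],
            prefix + "gamma": [gamma_scale * f for f in (0.1, 1.0, 10.0)],
        }
    if spec.family in ("logreg_l1", "logreg_l2"):
        return {prefix + "C": [0.01, 0.1, 1.0, 10.0]}
    if spec.family == "xgb":
        return {
            prefix + "max_depth": [2, 4, 6],
            prefix + "learning_rate": [0.05, 0.1, 0.3],
        }
    raise ContractError(f"family {spec.family!r} is not tuned")


def fit_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
              tune: bool = True) -> FittedModel:
    """Fit one spec on training rows.

    With ``spec.pca``, a train-fit PCA retaining the minimal number of
    components explaining 90% of the variance precedes the classifier.
    Tuned families run an inner stratified CV over the grid, maximizing
    mean inner AUC, then refit on all training rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        bad = sorted(set(np.where(~np.isfinite(X))[1].tolist()))
        raise ValidationError(f"non-finite values in feature columns {bad[:10]}")
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")

    seed = derive_seed(spec.seed, "model", spec.spec_id)
    est, score_kind = _base_estimator(spec, seed, X)
    if spec.pca:
        est = Pipeline([
            ("pca", PCA(n_components=0.90, svd_solver="full", random_state=seed)),
            ("clf", est),
        ])

    best_params = None
    if tune and spec.tuned:
        grid = spec.tuning_grid or _default_grid(spec, X)
        inner = StratifiedKFold(
            n_splits=spec.inner_cv_folds, shuffle=True,
            random_state=derive_seed(spec.seed, "inner_cv", spec.spec_id),
        )
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=inner,
                              n_jobs=1, refit=True)
        search.fit(X, y)
        est = search.best_estimator_
        best_params = dict(search.best_params_)
    else:
        est.fit(X, y)

    return FittedModel(spec=spec, estimator=est, n_features_in=X.shape[1],
                       score_kind=score_kind, best_params=best_params)


def predict_scores(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Real-valued decision scores, higher = more case-like."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in:
        raise ContractError(
            f"feature width {X.shape[1]} does not match training width "
            f"{model.n_features_in}"
        )
    est = model.estimator
    if model.score_kind == "margin":
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def score_threshold(score_kind: str) -> float:
    """Hard-label threshold: 0.5 for probabilities, 0 for margins."""
    return 0.5 if score_kind == "probability" else 0.0
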