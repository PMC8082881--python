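"""Gradient-boosted pair classifier and the baseline classifiers.

The production classifier is XGBoost configured with 1000 trees and learning
rate 0.1 (remaining parameters at the backend's defaults); it consumes NaN
feature values natively. AdaBoost (depth-10 decision-tree weak learner,
min_samples_split 5), random forest (depth 10, max_features 100) and an RBF
SVM (C=50) are provided for comparison; these cannot handle missing values,
so their inputs are mean-imputed with a logged warning.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any

import numpy as np

from .features import PairFeatureTable

logger = logging.getLogger(__name__)

__all__ = ["ClassifierConfig", "TrainedModel", "train_classifier", "predict_scores", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("gbdt", "adaboost", "random_forest", "svm")


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Classifier kind, overrides for its parameters, and a seed."""

    kind: str = "gbdt"
    params: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected {CLASSIFIER_KINDS}")


def _make_backend(config: ClassifierConfig, n_features: int):
    if config.kind == "gbdt":
        from xgboost import XGBClassifier

        params = dict(
            n_estimators=1000,
            learning_rate=0.1,
            tree_method="hist",
            n_jobs=1,
            random_state=config.seed,
        )
        params.update(config.params)
        return XGBClassifier(**params)
    if config.kind == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        params = dict(
            estimator=DecisionTreeClassifier(max_depth=10, min_samples_split=5),
            random_state=config.seed,
        )
        params.update(config.params)
        return AdaBoostClassifier(**params)
    if config.kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        params = dict(
            max_depth=10,
            max_features=min(100, n_features),
            random_state=config.seed,
            n_jobs=1,
        )
        params.update(config.params)
        return RandomForestClassifier(**params)
    # svm
    from sklearn.svm import SVC

    params = dict(kernel="rbf", C=50, probability=True, random_state=config.seed)
    params.update(config.params)
    return SVC(**params)


@dataclasses.dataclass
class TrainedModel:
    """Fitted backend plus everything needed to score new tables safely."""

    backend: Any
    config: ClassifierConfig
    train_width: int
    feature_meta: dict[str, Any]
    impute_means: np.ndarray | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.train_width:
            raise ValueError(
                f"feature width {X.shape[1]} does not match training width {self.train_width}"
            )
        if self.impute_means is not None:
            X = np.where(np.isnan(X), self.impute_means, X)
        return X


def train_classifier(table: PairFeatureTable, config: ClassifierConfig) -> TrainedModel:
    """Fit the configured classifier on a labelled feature table.

    Backends without native missing-value support get column-mean imputation
    (all-NaN columns fall back to 0), with a warning in the log.
    """
    if len(table) == 0:
        raise ValueError("feature table is empty")
    classes = np.unique(table.y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class ({classes})")

    X = table.X
    impute_means = None
    if config.kind != "gbdt" and np.isnan(X).any():
        logger.warning(
            "%s cannot handle missing values; imputing %d NaNs with column means",
            config.kind, int(np.isnan(X).sum()),
        )
        with np.errstate(all="ignore"):
            impute_means = np.nanmean(X, axis=0)
        impute_means = np.nan_to_num(impute_means, nan=0.0)
        X = np.where(np.isnan(X), impute_means, X)

    backend = _make_backend(config, table.width)
    backend.fit(X, table.y)
    return TrainedModel(
        backend=backend,
        config=config,
        train_width=table.width,
        feature_meta={"mode": table.mode, "block_offsets": dict(table.block_offsets)},
        impute_means=impute_means,
    )


def predict_scores(model: TrainedModel, table: PairFeatureTable) -> np.ndarray:
    """Probability-like association score in [0, 1] per row, order preserved."""
    if len(table) == 0:
        return np.empty(0)
    X = model._prepare(table.X)
    proba = model.backend.predict_proba(X)
    positive_col = list(model.backend.classes_).index(1)
    return proba[:, positive_col]
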