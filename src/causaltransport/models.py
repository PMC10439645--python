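"""Classifier families for the transportability experiment.

Four algorithms, matched to the experiment's documented settings:

* ``logistic`` — maximum-likelihood logistic regression, no penalty;
* ``lasso`` — L1-penalized logistic regression, penalty chosen by 10-fold
  seeded cross-validation minimizing deviance over 100 log-spaced values;
* ``random_forest`` — 500 trees, floor(sqrt(p)) candidate variables per split;
* ``gbm`` — 100 boosted depth-3 trees, learning rate 0.1, deviance loss.

Tree-ensemble probabilities are deliberately NOT recalibrated: their
miscalibration is part of the phenomenon under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .cohort import as_frame
from .graph import SCHEMES, CausalGraph
from .metrics import PredictionSet

ALGORITHMS = ("logistic", "lasso", "random_forest", "gbm")


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    algorithm: str
    scheme: str
    seed: int = 0
    lasso_n_penalties: int = 100
    lasso_cv_folds: int = 10
    rf_n_trees: int = 500
    gbm_n_trees: int = 100
    gbm_learning_rate: float = 0.1
    gbm_depth: int = 3

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ModelError(f"unknown algorithm {self.algorithm!r}")
        if self.scheme not in SCHEMES:
            raise ModelError(f"unknown predictor scheme {self.scheme!r}")


@dataclass
class FittedModel:
    """Opaque handle: estimator + resolved predictor list."""

    config: ModelConfig
    predictors: list[str]
    outcome: str
    estimator: object = field(repr=False)


def _make_estimator(config: ModelConfig):
    if config.algorithm == "logistic":
        # C=inf == unpenalized maximum likelihood
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if config.algorithm == "lasso":
        return LogisticRegressionCV(
            Cs=config.lasso_n_penalties, l1_ratios=(1.0,), solver="liblinear",
            scoring="neg_log_loss", use_legacy_attributes=False,
            cv=StratifiedKFold(config.lasso_cv_folds, shuffle=True,
                               random_state=config.seed),
            random_state=config.seed, max_iter=2000)
    if config.algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=config.rf_n_trees,
                                      max_features="sqrt",
                                      random_state=config.seed)
    return GradientBoostingClassifier(n_estimators=config.gbm_n_trees,
                                      learning_rate=config.gbm_learning_rate,
                                      max_depth=config.gbm_depth,
                                      random_state=config.seed)


def train_model(config: ModelConfig, train, graph: CausalGraph) -> FittedModel:
    """Fit one algorithm on the training cohort restricted to its scheme."""
    df = as_frame(train)
    predictors = graph.predictor_set(config.scheme)
    outcome = graph.outcome
    missing = [c for c in predictors + [outcome] if c not in df.columns]
    if missing:
        raise ModelError(f"training cohort lacks columns {missing}")
    y = np.asarray(df[outcome], dtype=float)
    if len(np.unique(y)) < 2:
        raise ModelError(f"outcome {outcome!r} has a single class in training data")
    X = df[predictors].to_numpy(dtype=float)
    est = _make_estimator(config)
    try:
        est.fit(X, y)
    except Exception as exc:
        raise ModelError(f"{config.algorithm} failed to converge/fit: {exc}")
    return FittedModel(config, list(predictors), outcome, est)


def predict_probabilities(model: FittedModel, data) -> PredictionSet:
    """Predicted event probabilities on a cohort (extra columns ignored)."""
    df = as_frame(data)
    missing = [c for c in model.predictors if c not in df.columns]
    if missing:
        raise ModelError(f"cohort lacks predictor columns {missing}")
    if model.outcome not in df.columns:
        raise ModelError(f"cohort lacks outcome column {model.outcome!r}")
    X = df[model.predictors].to_numpy(dtype=float)
    classes = list(getattr(model.estimator, "classes_", (0.0, 1.0)))
    probs = model.estimator.predict_proba(X)[:, classes.index(1.0)]
    setting = data.setting if hasattr(data, "setting") else ""
    return PredictionSet(np.clip(probs, 0.0, 1.0),
                         np.asarray(df[model.outcome], dtype=float), setting)
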