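"""Classical quality classifiers on the 45 SQI features.

Naive Bayes, linear / RBF support-vector machines and random forests are
fitted on the benchmark feature vectors, with hyper-parameters chosen by
an inner stratified-CV grid search maximizing AUC.  Features are
standardized (fit on training data only) for the NB and SVM pipelines and
left raw for the random forest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from fecgsqi.errors import ConfigError

__all__ = ["GridSpec", "DEFAULT_GRIDS", "train_benchmark", "predict_benchmark", "MODEL_TYPES"]

MODEL_TYPES = ("nb", "svm_linear", "svm_rbf", "rf")


@dataclass(frozen=True)
class GridSpec:
    """A model family plus its hyper-parameter search grid."""

    model_type: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ConfigError(f"model_type must be one of {MODEL_TYPES}")
        if any(len(v) == 0 for v in self.grid.values()):
            raise ConfigError("grid lists must be non-empty")

    def points(self) -> list[dict]:
        if not self.grid:
            return [{}]
        keys = sorted(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


DEFAULT_GRIDS = {
    "nb": GridSpec("nb", {"var_smoothing": [1e-9, 1e-7, 1e-5]}),
    "svm_linear": GridSpec("svm_linear", {"C": [0.1, 1.0, 10.0, 100.0]}),
    "svm_rbf": GridSpec("svm_rbf", {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [1e-3, 1e-2, 1e-1, "scale"]}),
    "rf": GridSpec(
        "rf",
        {"n_estimators": [100, 300], "max_depth": [None, 10, 20], "min_samples_leaf": [1, 5]},
    ),
}


def _make_estimator(model_type: str, params: dict, seed: int):
    if model_type == "nb":
        return Pipeline([("scale", StandardScaler()), ("clf", GaussianNB(**params))])
    if model_type == "svm_linear":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="linear", random_state=seed, **params))]
        )
    if model_type == "svm_rbf":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="rbf", random_state=seed, **params))]
        )
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def train_benchmark(
    features: np.ndarray,
    labels: np.ndarray,
    grid: GridSpec,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[object, dict, float]:
    """Grid search by inner stratified-CV mean AUC, then refit on all data.

    Returns ``(fitted_model, best_params, best_inner_auc)``.  Ties go to
    the earliest grid point in the (sorted-key) enumeration order.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ConfigError("training labels must contain both classes")
    if not np.all(np.isfinite(x)):
        raise ConfigError("features must be finite")

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    best_auc, best_params = -np.inf, None
    for params in grid.points():
        aucs = []
        for tr, va in splits:
            est = _make_estimator(grid.model_type, params, seed)
            est.fit(x[tr], y[tr])
            aucs.append(roc_auc_score(y[va], _scores(est, x[va])))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    model = _make_estimator(grid.model_type, best_params, seed)
    model.fit(x, y)
    model._fecgsqi_n_features = x.shape[1]
    return model, best_params, best_auc


def _scores(model, x: np.ndarray) -> np.ndarray:
    """Good-class score in [0, 1].

    SVMs expose a margin rather than a probability; the margin is mapped
    through a logistic so that 0.5 corresponds to the decision boundary
    and the ranking (hence AUC) is preserved.
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, list(model.classes_).index(1)]
    margin = model.decision_function(x)
    if list(model.classes_).index(1) == 0:
        margin = -margin
    return expit(margin)


def predict_benchmark(model, features: np.ndarray) -> np.ndarray:
    """Good-quality probability per row of the feature matrix."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    expected = getattr(model, "_fecgsqi_n_features", x.shape[1])
    if x.shape[0] == 0:
        return np.empty(0)
    if x.shape[1] != expected:
        raise ConfigError(f"feature layout mismatch: expected {expected} columns, got {x.shape[1]}")
    return _scores(model, x)
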