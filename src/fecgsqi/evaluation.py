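"""Nested stratified cross-validation, metrics and recording-level voting.

The evaluation protocol: an outer stratified K-fold loop holds out a test
fold; the remaining data enter an inner stratified K-fold loop used for
model selection (best-validation-AUC weights for the CNN, best grid point
for the classical learners); the selected model is evaluated once on the
held-out fold.  The procedure can be repeated with re-randomized folds
and is aggregated as mean ± sample standard deviation over all outer
evaluations.  The positive class is good quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from fecgsqi.benchmark import DEFAULT_GRIDS, GridSpec, predict_benchmark, train_benchmark
from fecgsqi.cnn import ArchConfig, TrainConfig, build_model, predict, train
from fecgsqi.errors import ConfigError

__all__ = [
    "FoldSpec",
    "CVResult",
    "stratified_folds",
    "nested_cv",
    "metrics",
    "error_rate_per_minute",
    "majority_vote",
]


@dataclass(frozen=True)
class FoldSpec:
    outer_k: int = 10
    inner_k: int = 5
    repetitions: int = 1
    stratified: bool = True
    grouping: str = "segment"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ConfigError("outer_k and inner_k must be >= 2")
        if self.grouping not in ("segment", "recording"):
            raise ConfigError("grouping must be 'segment' or 'recording'")


@dataclass
class CVResult:
    """Per-outer-fold metric records plus aggregates and confusion totals."""

    records: list = field(default_factory=list)

    def aggregate(self) -> dict:
        out: dict = {}
        for key in ("accuracy", "precision", "recall", "f1", "auc"):
            vals = np.array([r[key] for r in self.records], dtype=float)
            out[key] = {
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        for key in ("tp", "fp", "tn", "fn"):
            out[key] = int(sum(r[key] for r in self.records))
        return out


def stratified_folds(
    labels: np.ndarray,
    k: int,
    seed: int = 0,
    grouping: str = "segment",
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Fold index per item, class-balanced within one item per fold.

    With ``grouping='recording'`` all segments of a recording share a
    fold (grouped stratification).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if k > len(y) or (grouping == "segment" and k > counts.min()):
        raise ConfigError(f"k={k} too large for class counts {dict(zip(classes.tolist(), counts.tolist()))}")
    folds = np.empty(len(y), dtype=int)
    if grouping == "recording":
        if groups is None:
            raise ConfigError("grouping='recording' requires a groups array")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y, groups)):
            folds[test_idx] = f
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            folds[test_idx] = f
    return folds


def metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Confusion-based metrics at a threshold plus rank-statistic AUC.

    The positive class is good quality (label 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape:
        raise ConfigError("scores and labels must have equal length")
    if np.unique(y).size < 2:
        raise ConfigError("AUC undefined for single-class labels")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / y.size,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": float(roc_auc_score(y, scores)),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def error_rate_per_minute(fp: int, fn: int, total_minutes: float) -> tuple[float, float]:
    """False-positive and false-negative counts per minute of data."""
    if total_minutes <= 0:
        raise ConfigError("total_minutes must be positive")
    return fp / total_minutes, fn / total_minutes


def majority_vote(segment_labels) -> int:
    """Recording label from its segment labels; exact ties resolve to bad.

    Rejecting the borderline recording is preferable to accepting one
    that later proves useless.
    """
    labels = [int(l) for l in segment_labels]
    if not labels:
        raise ConfigError("majority_vote needs at least one segment label")
    n_good = sum(labels)
    return 1 if n_good > len(labels) - n_good else 0


def _select_cnn(
    images, y, inner_folds, arch: ArchConfig, tcfg: TrainConfig, seed: int
):
    """Inner loop for the CNN: one training run per inner fold, keep the
    weights whose best epoch had the highest validation AUC."""
    best_auc, best_weights, best_model = -np.inf, None, None
    for f in np.unique(inner_folds):
        tr, va = inner_folds != f, inner_folds == f
        model = build_model(arch, seed=seed + int(f))
        weights, history = train(
            model, images[tr], y[tr], images[va], y[va],
            TrainConfig(epochs=tcfg.epochs, batch_size=tcfg.batch_size,
                        learning_rate=tcfg.learning_rate, seed=seed + int(f)),
        )
        if history["best_val_auc"] > best_auc:
            best_auc = history["best_val_auc"]
            best_weights, best_model = weights, model
    best_model.set_weights(best_weights)
    return best_model


def nested_cv(
    features: np.ndarray,
    labels: np.ndarray,
    learner: str,
    spec: FoldSpec | None = None,
    groups: np.ndarray | None = None,
    arch: ArchConfig | None = None,
    train_config: TrainConfig | None = None,
    grid: GridSpec | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """Nested stratified CV for one learner.

    ``features`` is the image tensor ``(n, n_paths, 40, 126)`` for the
    ``cnn`` learner or the ``(n, 45)`` feature matrix for the classical
    learners (``nb``, ``svm_linear``, ``svm_rbf``, ``rf``).
    """
    spec = spec or FoldSpec()
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ConfigError("dataset must contain both classes")
    result = CVResult()
    out_scores = np.zeros(len(y))
    for rep in range(spec.repetitions):
        rep_seed = spec.seed + 1000 * rep
        outer = stratified_folds(y, spec.outer_k, seed=rep_seed, grouping=spec.grouping, groups=groups)
        for f in range(spec.outer_k):
            test = outer == f
            trainset = ~test
            x_tr, y_tr = features[trainset], y[trainset]
            g_tr = groups[trainset] if groups is not None else None
            if learner == "cnn":
                inner = stratified_folds(
                    y_tr, spec.inner_k, seed=rep_seed + f, grouping=spec.grouping, groups=g_tr
                )
                model = _select_cnn(
                    x_tr, y_tr, inner, arch or ArchConfig(), train_config or TrainConfig(),
                    seed=rep_seed + 17 * f,
                )
                scores = predict(model, features[test])
            else:
                model, _, _ = train_benchmark(
                    x_tr, y_tr, grid or DEFAULT_GRIDS[learner],
                    inner_folds=spec.inner_k, seed=rep_seed + f,
                )
                scores = predict_benchmark(model, features[test])
            rec = metrics(scores, y[test], threshold=threshold)
            rec.update({"repetition": rep, "fold": f})
            result.records.append(rec)
            if rep == spec.repetitions - 1:
                out_scores[test] = scores
    result.out_scores = out_scores
    return result
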