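"""Classifiers over DTI feature vectors.

The workhorse is a cascade deep forest: an ordered sequence of levels, each a
bag of forests (half random forests, half extremely randomized trees).  Level
``t > 1`` receives the original features augmented with the previous level's
out-of-fold class-probability vectors (one 2-vector per forest), and training
stops automatically when adding a level no longer improves the out-of-fold
validation metric.  Out-of-fold probabilities — never in-sample ones — feed
both the augmentation and the stopping trace, so the level count adapts to
the data without overfitting.

Logistic regression, a single random forest and an MLP are provided as
baselines behind the same ``predict_scores`` contract (scores = positive-class
probabilities in [0, 1]).  Tree models see raw features; logit and MLP get
z-scaling fit on the training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import (
    DegenerateLabelError,
    InvalidConfigError,
    InvalidInputError,
    ShapeError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade deep forest hyperparameters.

    Defaults mirror the optimized configuration (500 trees per forest, 8
    forests per level); ``cv_folds_internal`` controls the out-of-fold
    probability generation, ``stop_tolerance`` the minimum improvement that
    justifies another level.
    """

    n_estimators_per_level: int = 8
    n_trees: int = 500
    split_criterion: str = "gini"
    max_depth: int | None = None
    min_samples_split: int = 2
    max_features: str | int | float = "sqrt"
    min_impurity_decrease: float = 0.0
    cv_folds_internal: int = 3
    stop_tolerance: float = 1e-4
    max_levels: int = 20
    metric: str = "aupr"  # 'aupr' | 'auroc' | 'accuracy'
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators_per_level < 2 or self.n_estimators_per_level % 2:
            raise InvalidConfigError("n_estimators_per_level must be even and >= 2")
        if self.n_trees < 1:
            raise InvalidConfigError("n_trees must be >= 1")
        if self.stop_tolerance < 0:
            raise InvalidConfigError("stop_tolerance must be >= 0")
        if self.metric not in ("aupr", "auroc", "accuracy"):
            raise InvalidConfigError(f"unknown metric {self.metric!r}")


def _metric_fn(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if name == "aupr":
        return lambda y, p: float(average_precision_score(y, p))
    if name == "auroc":
        return lambda y, p: float(roc_auc_score(y, p))
    return lambda y, p: float(np.mean((p >= 0.5).astype(int) == y))


def _level_forests(config: CascadeConfig, level: int) -> list:
    """Instantiate one level's forests: half RF, half extra-trees."""
    half = config.n_estimators_per_level // 2
    common = dict(
        n_estimators=config.n_trees,
        criterion=config.split_criterion,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        max_features=config.max_features,
        min_impurity_decrease=config.min_impurity_decrease,
        n_jobs=1,
    )
    forests = []
    for i in range(half):
        forests.append(
            RandomForestClassifier(
                random_state=config.seed + 1000 * level + i, **common
            )
        )
    for i in range(half):
        forests.append(
            ExtraTreesClassifier(
                random_state=config.seed + 1000 * level + half + i, **common
            )
        )
    return forests


@dataclass
class CascadeForestModel:
    """Fitted cascade: ordered levels of forests plus the stopping trace."""

    config: CascadeConfig
    levels: list[list] = field(default_factory=list)
    level_scores: list[float] = field(default_factory=list)
    input_dim: int = 0
    n_classes: int = 2

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def _augment(self, X: np.ndarray, probas: np.ndarray | None) -> np.ndarray:
        return X if probas is None else np.hstack([X, probas])

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Mean positive-class probability over the last level's forests."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ShapeError(
                f"expected (*, {self.input_dim}) features, got {X.shape}"
            )
        probas = None
        for forests in self.levels:
            Xa = self._augment(X, probas)
            level_probas = [f.predict_proba(Xa) for f in forests]
            probas = np.hstack(level_probas)
        pos = np.mean(
            [p[:, 1] for p in np.split(probas, len(self.levels[-1]), axis=1)], axis=0
        )
        return pos


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelError("labels contain a single class")
    if not set(classes) <= {0, 1}:
        raise InvalidInputError("labels must be binary 0/1")
    return y


def fit_cascade(X: np.ndarray, y: np.ndarray, config: CascadeConfig) -> CascadeForestModel:
    """Fit a cascade deep forest with automatic level-count selection.

    Per level: each forest produces out-of-fold class probabilities via
    stratified k-fold, the level's validation score is the chosen metric on
    the forest-averaged out-of-fold positive-class probability, and each
    forest is then refit on the full data for prediction time.  Training
    stops when the score fails to improve on the best seen by more than
    ``stop_tolerance``; the best-scoring prefix of levels is kept.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if X.shape[0] != len(y):
        raise InvalidInputError("X and y length mismatch")
    if X.shape[0] < config.cv_folds_internal:
        raise InvalidInputError("fewer rows than internal CV folds")
    metric = _metric_fn(config.metric)
    model = CascadeForestModel(config=config, input_dim=X.shape[1])
    skf = StratifiedKFold(
        n_splits=config.cv_folds_internal, shuffle=True, random_state=config.seed
    )
    splits = list(skf.split(X, y))
    best_score, best_n_levels = -np.inf, 0
    oof_probas = None  # out-of-fold augmentation features for the next level
    for level in range(config.max_levels):
        forests = _level_forests(config, level)
        Xa = X if oof_probas is None else np.hstack([X, oof_probas])
        level_oof = np.zeros((X.shape[0], len(forests) * 2))
        for j, forest in enumerate(forests):
            oof = np.zeros((X.shape[0], 2))
            for train_idx, val_idx in splits:
                fold_forest = clone(forest)
                fold_forest.fit(Xa[train_idx], y[train_idx])
                oof[val_idx] = fold_forest.predict_proba(Xa[val_idx])
            level_oof[:, 2 * j : 2 * j + 2] = oof
            forest.fit(Xa, y)  # full-data fit kept for prediction
        pos_mean = level_oof[:, 1::2].mean(axis=1)
        score = metric(y, pos_mean)
        model.levels.append(forests)
        model.level_scores.append(score)
        logger.debug("cascade level %d: %s=%.4f", level + 1, config.metric, score)
        if level == 0 or score > best_score + config.stop_tolerance:
            best_score, best_n_levels = score, level + 1
        else:
            break
        # every metric is bounded by 1: if no attainable score can clear the
        # tolerance, training another level is provably futile
        if best_score + config.stop_tolerance >= 1.0:
            break
        oof_probas = level_oof
    model.levels = model.levels[:best_n_levels]
    model.level_scores = model.level_scores[:best_n_levels]
    return model


class BaselineModel:
    """Baseline classifier wrapped behind the predict_scores contract."""

    def __init__(self, kind: str, estimator, input_dim: int):
        self.kind = kind
        self.estimator = estimator
        self.input_dim = input_dim

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ShapeError(f"expected (*, {self.input_dim}) features, got {X.shape}")
        return self.estimator.predict_proba(X)[:, 1]


def fit_baseline(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0, **kwargs):
    """Fit a baseline: 'logit', 'rf' or 'mlp'.

    Logit and MLP are preceded by z-scaling fit on the training data; the
    random forest sees raw features.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if kind == "logit":
        est = make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed, **kwargs)
        )
    elif kind == "rf":
        params = dict(n_estimators=500, n_jobs=1)
        params.update(kwargs)
        est = RandomForestClassifier(random_state=seed, **params)
    elif kind == "mlp":
        params = dict(
            hidden_layer_sizes=(256, 64),
            early_stopping=True,
            validation_fraction=0.1,
            max_iter=300,
        )
        params.update(kwargs)
        est = make_pipeline(StandardScaler(), MLPClassifier(random_state=seed, **params))
    else:
        raise InvalidConfigError(f"unknown baseline kind {kind!r}")
    est.fit(X, y)
    return BaselineModel(kind, est, X.shape[1])


def grid_search(
    config_grid: Mapping[str, Sequence],
    base_config: CascadeConfig,
    score_fn: Callable[[CascadeConfig], float],
) -> tuple[CascadeConfig, list[dict]]:
    """Greedy coordinate hyperparameter search.

    Optimizes one axis at a time in the grid's declared order, holding all
    others at the current best; ties break to the first-listed value.
    Returns the best config and the full evaluation trace.
    """
    if not config_grid or any(len(v) == 0 for v in config_grid.values()):
        raise InvalidConfigError("empty hyperparameter grid")
    best = base_config
    trace: list[dict] = []
    cache: dict[tuple, float] = {}

    def evaluate(cfg: CascadeConfig) -> float:
        key = tuple(sorted((k, repr(getattr(cfg, k))) for k in config_grid))
        if key not in cache:
            cache[key] = score_fn(cfg)
        return cache[key]

    for axis, values in config_grid.items():
        axis_best_val, axis_best_score = None, -np.inf
        for value in values:
            cfg = replace(best, **{axis: value})
            score = evaluate(cfg)
            trace.append({"axis": axis, "value": value, "score": score})
            if score > axis_best_score:  # strict: ties keep first-listed
                axis_best_val, axis_best_score = value, score
        best = replace(best, **{axis: axis_best_val})
    return best, trace
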