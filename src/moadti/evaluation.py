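"""Evaluation protocol and virtual-screening utilities.

Repeated stratified cross-validation over positive DTI pairs with sampled
negatives (1:1 in training; 1:1 or 1:10 in testing to emulate the sparse
positives of real screening), AUROC / AUPR summaries, enrichment factors at a
fixed false-positive-rate budget, and the reference-distribution ranking used
to contextualize single predicted scores against a drug library.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .datasets import DTIDataset, DTIRecord, assemble_dataset, sample_negatives, split_folds
from .exceptions import EmptyInputError, InvalidInputError, UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts at one score threshold."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0 or self.total == 0:
            raise InvalidInputError("counts must be non-negative with total > 0")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else float("nan")

    @property
    def tpr(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def fpr(self) -> float:
        return self.FP / (self.FP + self.TN) if self.FP + self.TN else float("nan")

    @property
    def prevalence(self) -> float:
        return (self.TP + self.FN) / self.total


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InvalidInputError("scores and labels must be equal-length 1-D")
    if not set(np.unique(labels)) <= {0, 1}:
        raise InvalidInputError("labels must be binary 0/1")
    return scores, labels


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts with a positive call iff score >= threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    call = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(call & (labels == 1))),
        FP=int(np.sum(call & (labels == 0))),
        FN=int(np.sum(~call & (labels == 1))),
        TN=int(np.sum(~call & (labels == 0))),
    )


def roc_auc(scores, labels) -> float:
    """AUROC (equals the normalized Mann-Whitney U; ties at midrank)."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """AUPR by step integration of the precision-recall curve."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUPR undefined for single-class labels")
    return float(average_precision_score(labels, scores))


def enrichment_factor_from_counts(counts: ConfusionCounts) -> float:
    """EF at an operating point: precision divided by positive prevalence."""
    if np.isnan(counts.precision):
        return 0.0
    return counts.precision / counts.prevalence


def enrichment_factor(
    scores, labels, fpr_level: float, method: str = "conservative"
) -> float:
    """Enrichment factor at a false-positive-rate budget.

    ``conservative`` (default): the operating point is the largest threshold
    whose FPR does not exceed ``fpr_level``; EF = precision / prevalence
    there.  If no such non-empty operating point exists the value is 0 (with
    a warning) — except for a fully tied score vector, which carries no
    ranking information and is scored at chance level (EF = 1) via the
    diagonal-ROC interpolation.  ``interpolate``: linear interpolation of the
    ROC curve at exactly ``fpr_level``.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if not 0 < fpr_level < 1:
        raise InvalidInputError("fpr_level must be in (0, 1)")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("EF undefined for single-class labels")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    prevalence = n_pos / len(labels)
    fully_tied = len(np.unique(scores)) == 1

    def ef_at(tpr_val: float, fpr_val: float) -> float:
        tp = tpr_val * n_pos
        fp = fpr_val * n_neg
        if tp + fp == 0:
            return 0.0
        return (tp / (tp + fp)) / prevalence

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    if method == "interpolate" or (method == "conservative" and fully_tied):
        # a constant scorer's ROC is the diagonal: EF = 1 at every budget
        return ef_at(float(np.interp(fpr_level, fpr, tpr)), fpr_level)
    if method != "conservative":
        raise InvalidInputError(f"unknown EF method {method!r}")
    ok = (fpr <= fpr_level) & (tpr + fpr > 0)
    if not ok.any():
        warnings.warn(
            f"no non-empty operating point with FPR <= {fpr_level}; EF = 0",
            stacklevel=2,
        )
        return 0.0
    idx = np.max(np.nonzero(ok))  # largest calling set within the budget
    return ef_at(float(tpr[idx]), float(fpr[idx]))


@dataclass
class CVResult:
    """Per-fold cross-validation metrics with protocol metadata."""

    k: int
    repeats: int
    test_negative_ratio: int
    master_seed: int
    rows: list[dict] = field(default_factory=list)  # repeat, fold, auroc, aupr, ...

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> dict:
        df = self.to_frame()
        out = {
            "k": self.k,
            "repeats": self.repeats,
            "test_negative_ratio": self.test_negative_ratio,
            "master_seed": self.master_seed,
            "n_folds": len(self.rows),
        }
        for metric in ("auroc", "aupr", "ef1", "ef5"):
            if metric in df:
                out[f"mean_{metric}"] = float(df[metric].mean())
                out[f"sd_{metric}"] = float(df[metric].std(ddof=1)) if len(df) > 1 else 0.0
        return out

    def __eq__(self, other):
        return isinstance(other, CVResult) and (
            (self.k, self.repeats, self.test_negative_ratio, self.master_seed, self.rows)
            == (other.k, other.repeats, other.test_negative_ratio, other.master_seed, other.rows)
        )


def derive_seed(master_seed: int, *context: int) -> np.random.SeedSequence:
    """Named, reproducible seed derivation from the single master seed."""
    return np.random.SeedSequence(entropy=(int(master_seed), *map(int, context)))


def cross_validate(
    dataset: DTIDataset,
    fit_fn: Callable[[np.ndarray, np.ndarray, int], object],
    k: int = 5,
    repeats: int = 5,
    test_negative_ratio: int = 1,
    master_seed: int = 0,
    compound_store=None,
    target_store=None,
    ef_levels: Sequence[float] = (0.01, 0.05),
) -> CVResult:
    """Repeated k-fold CV over positives with per-fold negative sampling.

    Per repeat, positives are re-partitioned with a derived seed.  Per fold,
    the model trains on the held-in positives plus an equal number of sampled
    negatives and is tested on the held-out positives plus
    ``test_negative_ratio`` times as many fresh negatives.  ``fit_fn(X, y,
    seed)`` must return an object with ``predict_scores``.

    ``compound_store``/``target_store`` default to rebuilding features via
    the dataset's own feature rows; they are required because sampled
    negatives need feature assembly.
    """
    positives = dataset.positives()
    if len(positives) < k:
        raise InvalidInputError("not enough positives for the requested folds")
    if compound_store is None or target_store is None:
        raise InvalidInputError("compound_store and target_store are required")

    def featurize(records: list[DTIRecord]) -> np.ndarray:
        ds = assemble_dataset(records, compound_store, target_store, tier=dataset.tier)
        if len(ds.records) != len(records):
            raise InvalidInputError("sampled records failed feature assembly")
        return ds.X

    result = CVResult(k, repeats, test_negative_ratio, master_seed)
    for r in range(repeats):
        folds = split_folds(positives, k, seed=derive_seed(master_seed, r, 0, 0))
        for f in range(k):
            test_pos = folds[f]
            train_pos = [p for i, fold in enumerate(folds) if i != f for p in fold]
            train_neg = sample_negatives(
                train_pos, ratio=1, seed=derive_seed(master_seed, r, f, 1),
                universe=positives,
            )
            test_neg = sample_negatives(
                test_pos,
                ratio=test_negative_ratio,
                seed=derive_seed(master_seed, r, f, 2),
                universe=positives,
            )
            X_train = np.vstack([featurize(train_pos), featurize(train_neg)])
            y_train = np.r_[np.ones(len(train_pos)), np.zeros(len(train_neg))]
            X_test = np.vstack([featurize(test_pos), featurize(test_neg)])
            y_test = np.r_[np.ones(len(test_pos)), np.zeros(len(test_neg))]
            fit_seed = int(derive_seed(master_seed, r, f, 3).generate_state(1)[0] % (2**31))
            model = fit_fn(X_train, y_train, fit_seed)
            scores = model.predict_scores(X_test)
            row = {
                "repeat": r,
                "fold": f,
                "auroc": roc_auc(scores, y_test),
                "aupr": pr_auc(scores, y_test),
            }
            for level in ef_levels:
                row[f"ef{round(level * 100)}"] = enrichment_factor(scores, y_test, level)
            result.rows.append(row)
        logger.debug("cross_validate repeat %d done", r)
    return result


@dataclass(frozen=True)
class RankResult:
    """Position of a query score within a reference score distribution."""

    score: float
    rank: int
    top_percentage: float
    reference_size: int


def rank_against_reference(query_score: float, reference_scores) -> RankResult:
    """1-based optimistic rank among reference scores, descending.

    rank = 1 + number of reference scores strictly greater than the query
    (the query is assumed to be a member of the reference pool);
    top percentage = 100 * rank / reference size.
    """
    reference = np.asarray(reference_scores, dtype=float)
    if reference.size == 0:
        raise EmptyInputError("reference score distribution is empty")
    rank = int(np.sum(reference > query_score)) + 1
    return RankResult(
        score=float(query_score),
        rank=rank,
        top_percentage=100.0 * rank / reference.size,
        reference_size=int(reference.size),
    )


def rediscover(scores, threshold: float = 0.5) -> np.ndarray:
    """Rediscovery flags: strictly above threshold counts as rediscovered."""
    scores = np.asarray(scores, dtype=float)
    return scores > threshold
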