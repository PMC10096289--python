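"""Perturbational signatures and correlation-weighted consensus aggregation.

A *signature* is a z-score profile over a fixed landmark gene panel measured
after one genetic perturbation (cDNA overexpression or shRNA knockdown) in one
cell line under one dose/time condition.  Replicate signatures for the same
perturbed gene are collapsed into a single consensus *target vector* by
MODZ-style weighted averaging: each replicate is weighted by the sum of its
Spearman correlations to the other replicates, so outlying profiles are
down-weighted.

Formally, for signatures ``x_1..x_n`` let ``R`` be the pairwise Spearman
correlation matrix.  The weights are

    w = (R - I) j / (j' (R - I) j),        j = vector of ones,

and the consensus is ``x_agg = sum_t w_t x_t``.  Off-diagonal correlations are
floored at a small positive value before summing so that anti-correlated
replicates cannot produce negative or zero weight mass.

Aggregation of a target's full replicate set is two-staged: condition-level
replicates are collapsed within each cell line first, and the per-cell-line
consensus vectors are then combined, so a cell line with many replicates does
not dominate the final vector.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .exceptions import EmptyInputError, InvalidInputError

#: Default floor applied to off-diagonal Spearman correlations before the
#: weight sums; keeps every weight strictly positive.
DEFAULT_CORRELATION_FLOOR = 0.01

#: Perturbation kind -> mode of action of the matching drug interaction.
PERTURBATION_MODE = {"overexpression": "activatory", "knockdown": "inhibitory"}

MODES = ("activatory", "inhibitory")


@dataclass(frozen=True)
class GenePanel:
    """Ordered landmark gene axis shared by every signature in a study.

    The real L1000 landmark panel has 978 genes; any size works here.
    """

    gene_ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("gene panel ids must be unique")
        if len(self.gene_ids) == 0:
            raise InvalidInputError("gene panel must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices reordering ``genes`` onto this panel.

        Raises if any panel gene is missing: signatures are re-ordered onto
        the panel, never imputed.
        """
        pos = {g: i for i, g in enumerate(genes)}
        missing = [g for g in self.gene_ids if g not in pos]
        if missing:
            raise InvalidInputError(
                f"{len(missing)} panel genes missing from input "
                f"(first: {missing[:3]})"
            )
        return np.array([pos[g] for g in self.gene_ids], dtype=int)


@dataclass
class Signature:
    """One perturbational z-score profile with its experimental metadata."""

    values: np.ndarray
    perturbed_gene: str
    perturbation_kind: str  # 'overexpression' | 'knockdown'
    cell_line: str
    condition: str
    signature_id: str
    panel: GenePanel

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.panel):
            raise InvalidInputError(
                f"signature {self.signature_id!r}: expected length "
                f"{len(self.panel)}, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError(
                f"signature {self.signature_id!r} contains non-finite values"
            )
        if self.perturbation_kind not in PERTURBATION_MODE:
            raise InvalidInputError(
                f"unknown perturbation kind {self.perturbation_kind!r}"
            )

    @property
    def mode(self) -> str:
        """Mode of action this signature represents (activatory/inhibitory)."""
        return PERTURBATION_MODE[self.perturbation_kind]


@dataclass
class AggregationResult:
    """Consensus vector with the convex weights that produced it."""

    vector: np.ndarray
    weights: np.ndarray
    member_ids: list[str] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return len(self.weights)


def spearman_correlation(a, b) -> float:
    """Spearman rank correlation with average ranks for ties.

    Constant vectors (zero rank variance) are assigned correlation 0 rather
    than NaN, so downstream weight sums stay finite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("inputs must be equal-length 1-D vectors")
    if len(a) < 2:
        raise InvalidInputError("need at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("inputs must be finite")
    ra, rb = rankdata(a), rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.clip(((ra - ra.mean()) * (rb - rb.mean())).mean() / (sa * sb), -1.0, 1.0))


def _rank_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman matrix of the rows of X; constant rows correlate 0."""
    ranks = np.apply_along_axis(rankdata, 1, X)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / ranks.shape[1]
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def correlation_matrix(signatures: Sequence[Signature]) -> np.ndarray:
    """n x n pairwise Spearman matrix over a list of signatures."""
    if len(signatures) == 0:
        raise EmptyInputError("no signatures")
    panel = signatures[0].panel
    if any(s.panel is not panel and s.panel != panel for s in signatures[1:]):
        raise InvalidInputError("signatures reference different gene panels")
    X = np.vstack([s.values for s in signatures])
    return _rank_correlation_matrix(X)


def weighted_average_matrix(
    X: np.ndarray,
    floor: float = DEFAULT_CORRELATION_FLOOR,
    member_ids: Sequence[str] | None = None,
) -> AggregationResult:
    """Correlation-weighted average of the rows of ``X``.

    ``n = 1`` returns the row itself with weight 1; ``n = 2`` is forced to the
    simple mean (both floored row sums equal the single off-diagonal entry).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    ids = list(member_ids) if member_ids is not None else [str(i) for i in range(n)]
    if n == 0:
        raise EmptyInputError("cannot aggregate zero signatures")
    if len(ids) != n:
        raise InvalidInputError("member_ids length mismatch")
    if n == 1:
        return AggregationResult(X[0].copy(), np.array([1.0]), ids)
    if np.all(X == X[0]):
        # exact replicate idempotence: the convex combination of m identical
        # rows is the row itself, bit-for-bit
        return AggregationResult(X[0].copy(), np.full(n, 1.0 / n), ids)
    if n == 2:
        return AggregationResult(X.mean(axis=0), np.array([0.5, 0.5]), ids)
    R = np.maximum(_rank_correlation_matrix(X), floor)
    np.fill_diagonal(R, 0.0)  # exclude trivial self-correlation
    row_sums = R.sum(axis=1)
    w = row_sums / row_sums.sum()
    return AggregationResult(w @ X, w, ids)


def weighted_average(
    signatures: Sequence[Signature], floor: float = DEFAULT_CORRELATION_FLOOR
) -> AggregationResult:
    """Correlation-weighted average of replicate signatures (one stage)."""
    if len(signatures) == 0:
        raise EmptyInputError("cannot aggregate zero signatures")
    panel = signatures[0].panel
    if any(s.panel != panel for s in signatures[1:]):
        raise InvalidInputError("signatures reference different gene panels")
    X = np.vstack([s.values for s in signatures])
    return weighted_average_matrix(
        X, floor=floor, member_ids=[s.signature_id for s in signatures]
    )


def aggregate_target(
    signatures: Sequence[Signature],
    floor: float = DEFAULT_CORRELATION_FLOOR,
    single_stage: bool = False,
) -> AggregationResult:
    """Consensus vector for one (perturbed gene, perturbation kind).

    Two-stage: condition-level replicates are collapsed within each cell line
    first, then the per-cell-line consensus vectors are combined.  The
    returned weights are the outer-stage (per cell line) weights, keyed by
    cell line in ``member_ids``.  ``single_stage=True`` pools every replicate
    in one pass (diagnostic only; susceptible to cell-line skew).
    """
    if len(signatures) == 0:
        raise EmptyInputError("cannot aggregate zero signatures")
    genes = {s.perturbed_gene for s in signatures}
    kinds = {s.perturbation_kind for s in signatures}
    if len(genes) > 1 or len(kinds) > 1:
        raise InvalidInputError(
            f"signatures mix perturbed genes {genes} / kinds {kinds}"
        )
    if single_stage:
        return weighted_average(signatures, floor=floor)
    by_cell: OrderedDict[str, list[Signature]] = OrderedDict()
    for s in signatures:
        by_cell.setdefault(s.cell_line, []).append(s)
    cell_vectors = [
        weighted_average(group, floor=floor).vector for group in by_cell.values()
    ]
    return weighted_average_matrix(
        np.vstack(cell_vectors), floor=floor, member_ids=list(by_cell)
    )
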