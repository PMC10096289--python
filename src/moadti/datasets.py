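"""Labelled activatory/inhibitory DTI datasets and feature assembly.

Positive pairs come from a curated table of (compound, target gene, mode of
action term); the vocabulary maps activator/agonist to the activatory mode
and inhibitor/antagonist to the inhibitory mode, everything else is dropped.
Each surviving pair is featurized as the concatenation of the compound
embedding (length d) and the target consensus vector (length G), compound
first.

Dataset *tiers* follow target-vector provenance: ``original`` keeps targets
with measured vectors, ``additional`` keeps inferred-only targets, and
``integrated`` keeps either.  Negatives are sampled uniformly without
replacement from the compound x target grid of the positive set, excluding
same-mode positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compounds import CompoundStore
from .exceptions import (
    CapacityError,
    InvalidInputError,
    ParseError,
)
from .ppi import TargetVectorStore

logger = logging.getLogger(__name__)

#: Mode-of-action vocabulary (matched case-insensitively).
DEFAULT_MOA_VOCABULARY = {
    "activator": "activatory",
    "agonist": "activatory",
    "inhibitor": "inhibitory",
    "antagonist": "inhibitory",
}

TIERS = ("original", "additional", "integrated")


@dataclass(frozen=True)
class DTIRecord:
    """One labelled (compound, target, mode) pair."""

    compound_id: str
    target_gene: str
    mode: str  # 'activatory' | 'inhibitory'
    label: int  # 1 positive, 0 negative
    source: str = "known"  # 'known' | 'sampled'

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.compound_id, self.target_gene, self.mode)


@dataclass
class DTIDataset:
    """Records with their aligned feature matrix (rows match records)."""

    records: list[DTIRecord]
    X: np.ndarray
    tier: str
    mode: str
    compound_dim: int
    target_dim: int
    filtered_out: int = 0

    def __post_init__(self):
        if self.X.shape[0] != len(self.records):
            raise InvalidInputError("feature rows do not match record count")
        if self.X.shape[1] != self.compound_dim + self.target_dim:
            raise InvalidInputError("feature width != compound_dim + target_dim")

    @property
    def y(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def positives(self) -> list[DTIRecord]:
        return [r for r in self.records if r.label == 1]


def parse_dti_table(
    table: pd.DataFrame,
    moa_vocabulary: Mapping[str, str] = DEFAULT_MOA_VOCABULARY,
) -> dict[str, list[DTIRecord]]:
    """Positive DTIRecords by mode from (compound_id, target_gene, moa_term).

    Unmapped mode-of-action terms are dropped (count logged); duplicate
    (compound, target, mode) triples collapse to one record.
    """
    required = {"compound_id", "target_gene", "moa_term"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"DTI table missing columns: {sorted(missing)}")
    vocab = {k.lower(): v for k, v in moa_vocabulary.items()}
    out: dict[str, list[DTIRecord]] = {"activatory": [], "inhibitory": []}
    seen: set[tuple[str, str, str]] = set()
    n_dropped = 0
    for row in table.itertuples(index=False):
        mode = vocab.get(str(row.moa_term).strip().lower())
        if mode is None:
            n_dropped += 1
            continue
        rec = DTIRecord(str(row.compound_id), str(row.target_gene), mode, 1, "known")
        if rec.key in seen:
            continue
        seen.add(rec.key)
        out[mode].append(rec)
    if n_dropped:
        logger.info("parse_dti_table: dropped %d rows with unmapped MoA terms", n_dropped)
    return out


def _tier_vector(store: TargetVectorStore, gene: str, tier: str):
    """Target vector under the tier's provenance rule, or None."""
    if tier == "original":
        return store.get(gene, "measured").vector if store.has(gene, "measured") else None
    if tier == "additional":
        # inferred-only targets: genes whose vector exists solely by inference
        if store.has(gene, "inferred") and not store.has(gene, "measured"):
            return store.get(gene, "inferred").vector
        return None
    if tier == "integrated":
        return store.get(gene).vector if store.has(gene) else None
    raise InvalidInputError(f"unknown tier {tier!r}")


def assemble_dataset(
    records: Sequence[DTIRecord],
    compound_store: CompoundStore,
    target_store: TargetVectorStore,
    tier: str = "integrated",
) -> DTIDataset:
    """Keep records whose compound embeds and whose target has a vector of
    the tier's provenance; feature row = compound vector (+) target vector."""
    if tier not in TIERS:
        raise InvalidInputError(f"unknown tier {tier!r}")
    modes = {r.mode for r in records}
    if len(modes) > 1:
        raise InvalidInputError(f"records mix modes {modes}; assemble per mode")
    mode = modes.pop() if modes else target_store.mode
    d = compound_store.dim
    kept, rows = [], []
    G = None
    for rec in records:
        if not compound_store.has(rec.compound_id):
            continue
        tvec = _tier_vector(target_store, rec.target_gene, tier)
        if tvec is None:
            continue
        G = len(tvec)
        kept.append(rec)
        rows.append(np.concatenate([compound_store.vector(rec.compound_id), tvec]))
    if G is None:
        # empty result: recover G from any store entry for a valid shape
        genes = target_store.genes()
        G = len(target_store.get(genes[0]).vector) if genes else 0
    X = np.vstack(rows) if rows else np.empty((0, d + G))
    n_filtered = len(records) - len(kept)
    if n_filtered:
        logger.info("assemble_dataset(%s): filtered out %d/%d records",
                    tier, n_filtered, len(records))
    return DTIDataset(kept, X, tier, mode, d, G, filtered_out=n_filtered)


def sample_negatives(
    positives: Sequence[DTIRecord],
    ratio: int = 1,
    seed: int | np.random.SeedSequence = 0,
    universe: Sequence[DTIRecord] | None = None,
) -> list[DTIRecord]:
    """Uniform negative pairs from the positives' compound x target grid.

    Draws exactly ``ratio * len(positives)`` unique pairs without replacement
    from {compounds} x {targets} minus the same-mode positive pairs;
    reproducible for a given seed.  ``universe`` (default: ``positives``)
    supplies the grid and the excluded positive pairs — cross-validation
    passes the full positive set here so that fold-level negatives come from
    the whole dataset's drugs and targets.
    """
    if not positives:
        return []
    if int(ratio) != ratio or ratio < 1:
        raise InvalidInputError("ratio must be a positive integer")
    if universe is None:
        universe_records = list(positives)
    else:
        universe_records = list(universe)
    mode = positives[0].mode
    if any(p.mode != mode for p in list(positives) + universe_records):
        raise InvalidInputError("positives mix modes; sample per mode")
    compounds = sorted({p.compound_id for p in universe_records})
    targets = sorted({p.target_gene for p in universe_records})
    n_c, n_t = len(compounds), len(targets)
    c_idx = {c: i for i, c in enumerate(compounds)}
    t_idx = {t: i for i, t in enumerate(targets)}
    pos_cells = {
        (c_idx[p.compound_id], t_idx[p.target_gene])
        for p in universe_records
        if p.compound_id in c_idx and p.target_gene in t_idx
    }
    pos_flat = np.fromiter(
        (ci * n_t + ti for ci, ti in pos_cells), dtype=np.int64, count=len(pos_cells)
    )
    universe = np.setdiff1d(np.arange(n_c * n_t, dtype=np.int64), pos_flat)
    n_request = int(ratio) * len(positives)
    if n_request > len(universe):
        raise CapacityError(
            f"requested {n_request} negatives but universe holds only "
            f"{len(universe)} (shortfall {n_request - len(universe)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(universe, size=n_request, replace=False)
    return [
        DTIRecord(compounds[flat // n_t], targets[flat % n_t], mode, 0, "sampled")
        for flat in chosen
    ]


def split_folds(
    positives: Sequence[DTIRecord], k: int, seed: int | np.random.SeedSequence = 0
) -> list[list[DTIRecord]]:
    """Seeded partition of positives into k folds with sizes differing <= 1."""
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if len(positives) < k:
        raise InvalidInputError(f"{len(positives)} positives cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds: list[list[DTIRecord]] = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(positives[idx])
    return folds
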