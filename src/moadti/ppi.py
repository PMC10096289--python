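"""Target-space extension over a protein-protein interaction network.

Targets without a measured perturbational consensus vector can still be
represented: assuming that functionally interacting proteins have correlated
perturbational transcriptomes, a missing target vector is *inferred* as the
correlation-weighted average of the measured vectors of its direct PPI
neighbours.  Inference requires at least ``min_neighbors`` covered neighbours
(default 3) and uses one hop only — no propagation.

Edges come from a STRING-style table (protein1, protein2, combined score);
only edges above the confidence threshold (default 0.9 on the unit scale,
i.e. 900 on STRING's 0-1000 combined-score scale) are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import mannwhitneyu

from .exceptions import (
    EmptyInputError,
    InvalidConfigError,
    InvalidInputError,
    LookupMissError,
    ParseError,
)
from .signatures import (
    DEFAULT_CORRELATION_FLOOR,
    MODES,
    spearman_correlation,
    weighted_average_matrix,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_NEIGHBORS = 3

#: Declared score scales: name -> (max value, default threshold)
SCORE_SCALES = {"string": 1000.0, "unit": 1.0}


class PPIGraph:
    """Undirected PPI graph with per-edge confidence scores.

    Adjacency is stored symmetrically; self-loops are rejected.  Neighbour
    iteration is sorted so every traversal is deterministic.
    """

    def __init__(self):
        self._adj: dict[str, dict[str, float]] = {}

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise InvalidInputError(f"self-loop on {a!r}")
        self._adj.setdefault(a, {})[b] = score
        self._adj.setdefault(b, {})[a] = score

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def neighbors(self, gene: str) -> list[str]:
        if gene not in self._adj:
            raise LookupMissError(gene)
        return sorted(self._adj[gene])

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))


def build_ppi(
    edge_table: Iterable[tuple],
    score_threshold: float = 0.9,
    scale: str = "unit",
    id_map: Mapping[str, str] | None = None,
) -> PPIGraph:
    """Build a graph from (gene_a, gene_b, score) rows.

    Keeps strictly-greater-than-threshold edges, deduplicates (last score
    wins), and optionally maps protein identifiers to gene symbols through
    ``id_map`` (rows with unmapped ids are dropped and counted).
    """
    if scale not in SCORE_SCALES:
        raise InvalidConfigError(f"unknown score scale {scale!r}")
    max_score = SCORE_SCALES[scale]
    if not (0 <= score_threshold <= max_score):
        raise InvalidConfigError(
            f"threshold {score_threshold} outside declared scale [0, {max_score}]"
        )
    graph = PPIGraph()
    n_unmapped = 0
    for lineno, row in enumerate(edge_table, start=1):
        try:
            a, b, score = row[0], row[1], float(row[2])
        except (IndexError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed PPI edge row at line {lineno}: {row!r}") from exc
        if not (0 <= score <= max_score):
            raise ParseError(
                f"score {score} at line {lineno} outside declared scale"
            )
        if id_map is not None:
            if a not in id_map or b not in id_map:
                n_unmapped += 1
                continue
            a, b = id_map[a], id_map[b]
        if a != b and score > score_threshold:
            graph.add_edge(str(a), str(b), score)
    if n_unmapped:
        logger.info("build_ppi: dropped %d rows with unmapped identifiers", n_unmapped)
    return graph


@dataclass
class TargetVector:
    """Consensus vector for one gene with its provenance."""

    vector: np.ndarray
    provenance: str  # 'measured' | 'inferred'
    n_support: int = 1


@dataclass
class TargetVectorStore:
    """Per-mode map from gene symbol to consensus target vector.

    A gene may hold both a measured and an inferred entry; plain lookup
    prefers measured.
    """

    mode: str
    entries: dict[str, dict[str, TargetVector]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidInputError(f"unknown mode {self.mode!r}")

    def add(self, gene: str, vector: np.ndarray, provenance: str, n_support: int = 1):
        if provenance not in ("measured", "inferred"):
            raise InvalidInputError(f"unknown provenance {provenance!r}")
        vector = np.asarray(vector, dtype=float)
        for existing in self._all_vectors():
            if len(existing) != len(vector):
                raise InvalidInputError("vector length differs from store contents")
            break
        self.entries.setdefault(gene, {})[provenance] = TargetVector(
            vector, provenance, n_support
        )

    def _all_vectors(self):
        for slots in self.entries.values():
            for tv in slots.values():
                yield tv.vector

    def get(self, gene: str, provenance: str | None = None) -> TargetVector:
        """Measured entry if present, else inferred; or a specific provenance."""
        slots = self.entries.get(gene)
        if not slots:
            raise LookupMissError(gene)
        if provenance is not None:
            if provenance not in slots:
                raise LookupMissError(f"{gene} ({provenance})")
            return slots[provenance]
        return slots.get("measured") or slots["inferred"]

    def has(self, gene: str, provenance: str | None = None) -> bool:
        slots = self.entries.get(gene, {})
        return bool(slots) if provenance is None else provenance in slots

    def genes(self, provenance: str | None = None) -> list[str]:
        if provenance is None:
            return sorted(self.entries)
        return sorted(g for g, slots in self.entries.items() if provenance in slots)


def infer_vector(
    gene: str,
    graph: PPIGraph,
    store: TargetVectorStore,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    floor: float = DEFAULT_CORRELATION_FLOOR,
) -> TargetVector | None:
    """Infer a target vector from measured PPI-neighbour vectors.

    Returns ``None`` when fewer than ``min_neighbors`` neighbours carry a
    measured vector.  The gene's own measured vector, if any, never
    participates.
    """
    covered = [
        nb for nb in graph.neighbors(gene)
        if nb != gene and store.has(nb, "measured")
    ]
    if len(covered) < min_neighbors:
        return None
    X = np.vstack([store.get(nb, "measured").vector for nb in covered])
    agg = weighted_average_matrix(X, floor=floor, member_ids=covered)
    return TargetVector(agg.vector, "inferred", n_support=len(covered))


def infer_all(
    graph: PPIGraph,
    store: TargetVectorStore,
    genes: Iterable[str] | None = None,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    floor: float = DEFAULT_CORRELATION_FLOOR,
) -> TargetVectorStore:
    """Extended copy of ``store`` with inferred entries for eligible genes.

    By default every graph node is attempted (including measured genes, so
    that inferred-vs-measured validation pairs exist).
    """
    out = TargetVectorStore(store.mode)
    for g, slots in store.entries.items():
        for tv in slots.values():
            out.add(g, tv.vector, tv.provenance, tv.n_support)
    for gene in sorted(genes) if genes is not None else graph.nodes:
        if gene not in graph:
            continue
        tv = infer_vector(gene, graph, store, min_neighbors=min_neighbors, floor=floor)
        if tv is not None:
            out.add(gene, tv.vector, "inferred", tv.n_support)
    return out


def inference_validation(
    store_measured: TargetVectorStore, store_inferred: TargetVectorStore
) -> dict:
    """Within-gene vs between-gene agreement of inferred vectors.

    For every gene with both a measured and an inferred vector, computes the
    Spearman correlation between the two ("within"); "between" pairs
    correlate each gene's inferred vector with every *other* gene's measured
    vector.  A one-sided Mann-Whitney rank-sum test asks whether within-gene
    correlations are stochastically larger.
    """
    genes = [
        g
        for g in store_measured.genes("measured")
        if store_inferred.has(g, "inferred")
    ]
    if not genes:
        raise InvalidInputError("no gene holds both a measured and an inferred vector")
    within = np.array(
        [
            spearman_correlation(
                store_inferred.get(g, "inferred").vector,
                store_measured.get(g, "measured").vector,
            )
            for g in genes
        ]
    )
    between = []
    for g in genes:
        inf_vec = store_inferred.get(g, "inferred").vector
        for h in genes:
            if h != g:
                between.append(
                    spearman_correlation(
                        inf_vec, store_measured.get(h, "measured").vector
                    )
                )
    between = np.array(between)
    if len(between):
        stat, pvalue = mannwhitneyu(within, between, alternative="greater")
    else:
        stat, pvalue = np.nan, np.nan
    return {
        "within": within,
        "between": between,
        "n_genes": len(genes),
        "median_within": float(np.median(within)),
        "median_between": float(np.median(between)) if len(between) else np.nan,
        "statistic": float(stat),
        "pvalue": float(pvalue),
    }
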