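"""Synthetic study generator: every input the pipeline needs, from one seed.

Emulates the statistical structure the method assumes, at desk scale:

* replicate perturbational signatures — per target, a true vector drawn from
  N(0, I_G) and one noisy replicate per (cell line, condition) cell;
* a PPI graph whose neighbours carry correlated copies of each target's true
  vector (plus decoy edges), so PPI inference has a planted structure to
  recover;
* a random Morgan-token embedding table and compounds as random token
  multisets;
* a DTI benchmark with a planted, learnable compound-target signal: pair
  propensity combines additive compound/target main effects with a bilinear
  interaction c'Wt, and the top pairs by noisy propensity become positives.

Everything is deterministic given the config seed.  The generator does not
emulate L1000 technology noise (beadset effects, dose-response shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compounds import CompoundRecord, CompoundStore, EmbeddingTable, embed_compound
from .datasets import DTIRecord
from .exceptions import InvalidConfigError
from .ppi import PPIGraph, TargetVectorStore
from .signatures import GenePanel, Signature

MODE_KIND = {"activatory": "overexpression", "inhibitory": "knockdown"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale knobs for the synthetic generator.

    Defaults are the desk-scale study conditions: a 50-gene panel, 30
    targets with a 3 cell-line x 3 condition replicate grid at noise SD 0.5,
    16-dimensional compound embeddings over 200 compounds, and 500 positive
    pairs planted with a mixed additive + bilinear signal.
    """

    G: int = 50
    n_targets: int = 30
    cells_per_target: int = 3
    conditions_per_cell: int = 3
    noise_sd: float = 0.5
    ppi_degree: int = 4
    neighbor_noise_sd: float = 0.5
    d: int = 16
    n_compounds: int = 200
    tokens_per_compound: int = 8
    vocabulary_size: int = 64
    n_positives: int = 500
    signal_strength: float = 1.0
    interaction_mix: float = 0.3
    propensity_slope: float = 4.0
    label_noise_sd: float = 1.0
    mode: str = "inhibitory"
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.G, self.n_targets, self.cells_per_target,
            self.conditions_per_cell, self.d, self.n_compounds,
            self.n_positives, self.ppi_degree,
        )
        if min(counts) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if self.noise_sd < 0 or self.label_noise_sd < 0:
            raise InvalidConfigError("noise SDs must be >= 0")
        if not 0 <= self.signal_strength <= 1:
            raise InvalidConfigError("signal_strength must be in [0, 1]")
        if not 0 <= self.interaction_mix <= 1:
            raise InvalidConfigError("interaction_mix must be in [0, 1]")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed, stream))
    )


def target_names(config: SyntheticConfig) -> list[str]:
    return [f"T{i:03d}" for i in range(config.n_targets)]


def gen_panel(config: SyntheticConfig) -> GenePanel:
    return GenePanel(tuple(f"G{i:03d}" for i in range(config.G)))


def gen_signatures(
    config: SyntheticConfig,
) -> tuple[list[Signature], dict[str, np.ndarray], GenePanel]:
    """Replicate signatures plus the ground-truth target vectors.

    Per target: truth ~ N(0, I_G); replicate (cell c, condition j) =
    truth + N(0, noise_sd^2 I).
    """
    rng = _rng(config, 1)
    panel = gen_panel(config)
    kind = MODE_KIND[config.mode]
    signatures: list[Signature] = []
    truths: dict[str, np.ndarray] = {}
    for gene in target_names(config):
        truth = rng.normal(size=config.G)
        truths[gene] = truth
        for c in range(config.cells_per_target):
            for j in range(config.conditions_per_cell):
                values = truth + config.noise_sd * rng.normal(size=config.G)
                signatures.append(
                    Signature(
                        values=values,
                        perturbed_gene=gene,
                        perturbation_kind=kind,
                        cell_line=f"CELL{c}",
                        condition=f"cond{j}",
                        signature_id=f"{gene}:CELL{c}:cond{j}",
                        panel=panel,
                    )
                )
    return signatures, truths, panel


def gen_ppi(
    config: SyntheticConfig, truths: dict[str, np.ndarray]
) -> tuple[PPIGraph, TargetVectorStore]:
    """Planted-neighbourhood PPI graph plus the neighbour vector store.

    Each target gene gets ``ppi_degree`` dedicated neighbour genes whose
    vectors are correlated copies (truth + N(0, neighbor_noise_sd^2 I)), plus
    one decoy edge to an uncovered gene, so low-degree nodes exist.
    """
    rng = _rng(config, 2)
    graph = PPIGraph()
    store = TargetVectorStore(config.mode)
    for gene, truth in truths.items():
        for k in range(config.ppi_degree):
            nb = f"{gene}_NB{k}"
            graph.add_edge(gene, nb, 950.0)
            store.add(
                nb,
                truth + config.neighbor_noise_sd * rng.normal(size=config.G),
                "measured",
            )
        # decoy: an edge to a gene with no measured vector and degree 1
        graph.add_edge(gene, f"{gene}_DECOY", 950.0)
    return graph, store


def gen_compounds(
    config: SyntheticConfig,
) -> tuple[EmbeddingTable, CompoundStore]:
    """Random token embedding table and compounds as random token multisets."""
    rng = _rng(config, 3)
    tokens = [str(2_000_000 + t) for t in range(config.vocabulary_size)]
    table = EmbeddingTable(
        {t: rng.normal(size=config.d) / np.sqrt(config.tokens_per_compound)
         for t in tokens}
    )
    store = CompoundStore(dim=config.d)
    for i in range(config.n_compounds):
        sentence = list(rng.choice(tokens, size=config.tokens_per_compound, replace=True))
        vec = embed_compound(sentence, table)
        store.add(CompoundRecord(f"C{i:04d}", "", sentence, vec))
    return table, store


def gen_dti_benchmark(
    config: SyntheticConfig,
    compound_store: CompoundStore,
    truths: dict[str, np.ndarray],
) -> tuple[list[DTIRecord], dict]:
    """Positive DTI pairs with a planted, learnable signal.

    Pair propensity = slope * s * z + noise, where z standardizes
    (1 - mix) * additive main effects + mix * bilinear interaction c'Wt and
    s is the signal strength; the ``n_positives`` top-propensity pairs are
    labelled positive.  The additive component keeps the signal recoverable
    by a linear model on concatenated features (an interaction alone is not),
    while the bilinear term rewards models that capture feature interactions.
    """
    rng = _rng(config, 4)
    cids = compound_store.ids()
    genes = sorted(truths)
    C = np.vstack([compound_store.vector(c) for c in cids])
    T = np.vstack([truths[g] for g in genes])
    W = rng.normal(size=(config.d, config.G))
    a = rng.normal(size=config.d)
    b = rng.normal(size=config.G)

    def standardize(M):
        return (M - M.mean()) / M.std()

    interaction = standardize(C @ W @ T.T)
    main = standardize((C @ a)[:, None] + (T @ b)[None, :])
    z = standardize(
        (1 - config.interaction_mix) * main + config.interaction_mix * interaction
    )
    noise = config.label_noise_sd * rng.normal(size=z.shape)
    propensity = config.propensity_slope * config.signal_strength * z + noise
    order = np.argsort(-propensity, axis=None, kind="stable")
    n_t = len(genes)
    positives = [
        DTIRecord(cids[flat // n_t], genes[flat % n_t], config.mode, 1, "known")
        for flat in order[: config.n_positives]
    ]
    truth_info = {
        "W": W, "a": a, "b": b, "propensity": propensity,
        "compound_ids": cids, "target_genes": genes,
    }
    return positives, truth_info


@dataclass
class SyntheticStudy:
    """A fully generated study bundle."""

    config: SyntheticConfig
    panel: GenePanel
    signatures: list[Signature]
    truths: dict[str, np.ndarray]
    graph: PPIGraph
    neighbor_store: TargetVectorStore
    table: EmbeddingTable
    compound_store: CompoundStore
    positives: list[DTIRecord]
    truth_info: dict = field(repr=False, default_factory=dict)


def gen_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate every pipeline input for one study under one seed."""
    signatures, truths, panel = gen_signatures(config)
    graph, neighbor_store = gen_ppi(config, truths)
    table, compound_store = gen_compounds(config)
    positives, truth_info = gen_dti_benchmark(config, compound_store, truths)
    return SyntheticStudy(
        config=config,
        panel=panel,
        signatures=signatures,
        truths=truths,
        graph=graph,
        neighbor_store=neighbor_store,
        table=table,
        compound_store=compound_store,
        positives=positives,
        truth_info=truth_info,
    )
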