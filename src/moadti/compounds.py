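"""Compound featurization: substructure sentences, embeddings, fingerprints.

A molecule is rendered as a "sentence" of Morgan substructure identifiers
(one token per heavy atom per radius, radii 0 and 1 by default, the mol2vec
scheme), and embedded as the sum of the per-token vectors looked up in a
pretrained token -> R^d table.  Hashed Morgan bit vectors and MACCS keys are
available as binary baselines.

The embedding table is an input artifact; training it is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator, rdmolops

from .exceptions import InvalidConfigError, InvalidInputError, StructureParseError

logger = logging.getLogger(__name__)

DEFAULT_RADII = (0, 1)
DEFAULT_EMBEDDING_DIM = 300


def _canonical_mol(smiles: str) -> Chem.Mol:
    """Parse SMILES, keep the largest covalent fragment, renumber atoms
    canonically so the emitted sentence is spelling-invariant."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    frags = rdmolops.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise StructureParseError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of the largest covalent fragment."""
    return Chem.MolToSmiles(_canonical_mol(smiles))


def mol_sentence(smiles: str, radii: Sequence[int] = DEFAULT_RADII) -> list[str]:
    """Morgan substructure sentence: per heavy atom, the environment
    identifier at each requested radius, radii ascending, atoms in canonical
    order.  Tokens are the unsigned identifiers rendered as strings.
    """
    radii = sorted(set(int(r) for r in radii))
    if not radii or radii[0] < 0:
        raise InvalidConfigError("radii must be non-negative integers")
    mol = _canonical_mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radii[-1])
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    env: dict[tuple[int, int], int] = {}
    for identifier, hits in ao.GetBitInfoMap().items():
        for atom_idx, radius in hits:
            env[(atom_idx, radius)] = identifier
    sentence = []
    for atom_idx in range(mol.GetNumAtoms()):
        for r in radii:
            if (atom_idx, r) in env:
                sentence.append(str(env[(atom_idx, r)]))
    return sentence


@dataclass
class EmbeddingTable:
    """Morgan-token -> R^d lookup with an unknown-token policy."""

    vectors: dict[str, np.ndarray]
    unk_policy: str = "skip"  # 'skip' | 'zero'

    def __post_init__(self):
        if self.unk_policy not in ("skip", "zero"):
            raise InvalidConfigError(f"unknown unk policy {self.unk_policy!r}")
        if not self.vectors:
            raise InvalidInputError("embedding table is empty")
        dims = {len(v) for v in self.vectors.values()}
        if len(dims) != 1:
            raise InvalidInputError(f"mixed embedding dimensions: {sorted(dims)}")
        self.vectors = {t: np.asarray(v, dtype=float) for t, v in self.vectors.items()}

    @property
    def dim(self) -> int:
        return len(next(iter(self.vectors.values())))

    def __contains__(self, token: str) -> bool:
        return token in self.vectors


def embed_compound(sentence: Iterable[str], table: EmbeddingTable) -> np.ndarray:
    """Sum of token embeddings, duplicates counted with multiplicity.

    Unknown tokens contribute nothing under the 'skip' policy (a zero vector
    under 'zero'); a sentence with no known token yields the zero vector with
    a warning.
    """
    out = np.zeros(table.dim)
    n_known = 0
    n_tokens = 0
    for token in sentence:
        n_tokens += 1
        if token in table:
            out += table.vectors[token]
            n_known += 1
    if n_tokens and n_known == 0:
        logger.warning("embed_compound: no sentence token found in table")
    return out


def fingerprint(
    smiles: str, kind: str = "morgan", n_bits: int = 2048, radius: int = 2
) -> np.ndarray:
    """Binary fingerprint baseline: hashed Morgan bits or 166-bit MACCS keys."""
    mol = _canonical_mol(smiles)
    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        return np.array(gen.GetFingerprint(mol), dtype=np.uint8)
    if kind == "maccs":
        bits = np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.uint8)
        return bits[1:]  # RDKit pads an unused bit 0; keys are 1..166
    raise InvalidConfigError(f"unknown fingerprint kind {kind!r}")


@dataclass
class CompoundRecord:
    """One compound with its sentence and summed embedding vector."""

    compound_id: str
    smiles: str  # canonical form of the largest fragment
    sentence: list[str]
    vector: np.ndarray


@dataclass
class CompoundStore:
    """Map compound id -> CompoundRecord with a fixed embedding dimension."""

    dim: int
    records: dict[str, CompoundRecord] = field(default_factory=dict)

    def add(self, record: CompoundRecord):
        if len(record.vector) != self.dim:
            raise InvalidInputError(
                f"compound {record.compound_id!r}: vector dim "
                f"{len(record.vector)} != store dim {self.dim}"
            )
        self.records[record.compound_id] = record

    def has(self, compound_id: str) -> bool:
        return compound_id in self.records

    def vector(self, compound_id: str) -> np.ndarray:
        return self.records[compound_id].vector

    def ids(self) -> list[str]:
        return sorted(self.records)


def featurize_compounds(
    smiles_by_id: Mapping[str, str],
    table: EmbeddingTable,
    radii: Sequence[int] = DEFAULT_RADII,
) -> tuple[CompoundStore, dict[str, str]]:
    """Embed every compound; returns the store and {id: reason} for failures.

    Unparseable structures are dropped (reported, not fatal); per-compound
    unknown-token rates are logged at debug level.
    """
    store = CompoundStore(dim=table.dim)
    failed: dict[str, str] = {}
    for cid in sorted(smiles_by_id):
        smi = smiles_by_id[cid]
        try:
            sentence = mol_sentence(smi, radii=radii)
        except StructureParseError as exc:
            failed[cid] = str(exc)
            continue
        n_unk = sum(1 for t in sentence if t not in table)
        if sentence and n_unk:
            logger.debug(
                "compound %s: %d/%d unknown tokens", cid, n_unk, len(sentence)
            )
        vec = embed_compound(sentence, table)
        store.add(CompoundRecord(cid, canonical_smiles(smi), sentence, vec))
    if failed:
        logger.info("featurize_compounds: %d structures failed to parse", len(failed))
    return store, failed
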