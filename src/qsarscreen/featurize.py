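"""Substructure-embedding featurization (mol2vec-style).

A molecule is tokenised into a "sentence" of per-atom Morgan circular-
environment identifiers (radius 0 then radius 1 per atom, canonical atom
order), and its feature vector is the sum of the per-identifier embedding
vectors. Embeddings come either from a pre-trained table in a plain-text
key→vector format, or from a deterministic hashed fallback table that maps
any identifier to a reproducible unit-variance pseudo-random vector — so the
whole pipeline runs without downloading trained weights.
"""
from __future__ import annotations

import hashlib

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError, SmilesParseError, QsarScreenError

DEFAULT_DIMENSION = 300
DEFAULT_RADII = (0, 1)


def _mol_from_smiles(smiles: str):
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    # round-trip through canonical SMILES so atom order (hence sentence order)
    # is identical for every input spelling of the same molecule
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def substructure_sentence(smiles: str, radii=DEFAULT_RADII) -> list[int]:
    """Tokenise a molecule into per-atom Morgan environment identifiers.

    For each heavy atom, identifiers at each requested radius are emitted in
    ascending-radius order; atoms follow canonical order. Redundant
    environments are kept, so symmetry-equivalent atoms carry equal
    identifiers at every radius; an atom whose environment stops growing
    before the largest radius (an isolated atom) reuses its largest available
    identifier, so every atom contributes len(radii) tokens."""
    from rdkit.Chem import rdFingerprintGenerator

    radii = tuple(sorted(radii))
    if any(r < 0 for r in radii):
        raise ParameterError("radii must be non-negative")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=max(radii), includeRedundantEnvironments=True
    )
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=out)
    per_atom: dict[int, dict[int, int]] = {a.GetIdx(): {} for a in mol.GetAtoms()}
    for identifier, hits in out.GetBitInfoMap().items():
        for atom_idx, radius in hits:
            per_atom[atom_idx][radius] = identifier
    sentence = []
    for atom_idx in sorted(per_atom):
        by_radius = per_atom[atom_idx]
        for r in radii:
            available = [rr for rr in by_radius if rr <= r]
            if not available:
                raise QsarScreenError(
                    f"no environment identifier for atom {atom_idx} at radius {r}"
                )
            sentence.append(by_radius[max(available)])
    return sentence


class EmbeddingTable:
    """identifier → vector lookup with a total domain (unknown → unk_vector)."""

    def __init__(self, entries: dict, dimension: int, unk_vector: np.ndarray | None = None):
        self.dimension = int(dimension)
        self.entries = {}
        for key, vec in entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ParameterError(
                    f"vector for key {key!r} has length {vec.size}, expected {self.dimension}"
                )
            self.entries[str(key)] = vec
        if unk_vector is None:
            unk_vector = np.zeros(self.dimension)
        self.unk_vector = np.asarray(unk_vector, dtype=float)
        if self.unk_vector.shape != (self.dimension,):
            raise ParameterError("unk_vector dimension mismatch")

    def lookup(self, identifier) -> np.ndarray:
        return self.entries.get(str(identifier), self.unk_vector)

    def __len__(self) -> int:
        return len(self.entries)

    def provenance(self) -> dict:
        return {"kind": "file", "dimension": self.dimension, "n_entries": len(self)}


class HashedEmbeddingTable(EmbeddingTable):
    """Deterministic fallback table: each identifier maps to a standard-normal
    vector seeded by a stable hash of (identifier, seed), identical across
    runs, processes and platforms."""

    def __init__(self, dimension: int = DEFAULT_DIMENSION, seed: int = 42):
        if dimension < 1:
            raise ParameterError("dimension must be at least 1")
        super().__init__({}, dimension)
        self.seed = int(seed)

    def lookup(self, identifier) -> np.ndarray:
        key = f"{identifier}|{self.seed}".encode()
        digest = hashlib.sha256(key).digest()
        stream_seed = int.from_bytes(digest[:8], "little")
        rng = np.random.default_rng(stream_seed)
        return rng.standard_normal(self.dimension)

    def provenance(self) -> dict:
        return {"kind": "hashed", "dimension": self.dimension, "seed": self.seed}


def hashed_embedding_table(dimension: int = DEFAULT_DIMENSION, seed: int = 42) -> HashedEmbeddingTable:
    return HashedEmbeddingTable(dimension=dimension, seed=seed)


def embed_compound(sentence, table: EmbeddingTable) -> np.ndarray:
    """Compound vector = Σ substructure vectors; empty sentence → zero vector."""
    out = np.zeros(table.dimension)
    for identifier in sentence:
        out = out + table.lookup(identifier)
    return out


def save_embedding_table(table: EmbeddingTable, path) -> None:
    """Write the documented plain-text format: one 'identifier v1 … vd' line
    per entry (the UNK vector under the key UNK)."""
    with open(path, "w") as fh:
        fh.write(f"UNK {' '.join(repr(float(v)) for v in table.unk_vector)}\n")
        for key, vec in table.entries.items():
            fh.write(f"{key} {' '.join(repr(float(v)) for v in vec)}\n")


def load_embedding_table(path) -> EmbeddingTable:
    """Load a plain-text embedding table; the dimension is inferred from the
    first line and every vector is validated against it."""
    entries: dict[str, np.ndarray] = {}
    unk = None
    dimension = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key, values = parts[0], parts[1:]
            vec = np.array([float(v) for v in values])
            if dimension is None:
                dimension = vec.size
                if dimension < 1:
                    raise ParameterError(f"line {lineno}: empty vector for key {key!r}")
            if vec.size != dimension:
                raise ParameterError(
                    f"ragged vector for key {key!r} (line {lineno}): "
                    f"length {vec.size}, expected {dimension}"
                )
            if key == "UNK":
                unk = vec
            else:
                entries[key] = vec
    if dimension is None:
        raise ParameterError("embedding table file is empty")
    return EmbeddingTable(entries, dimension, unk_vector=unk)


class Mol2VecFeaturizer(BaseEstimator, TransformerMixin):
    """Transform SMILES into fixed-length vectors by summing substructure
    embeddings.

    Parameters
    ----------
    dimension : int
        Feature vector length (ignored when a table file supplies its own).
    radii : tuple of int
        Morgan environment radii per atom.
    seed : int
        Seed of the hashed fallback table.
    table_path : str or None
        Optional path to a pre-trained plain-text embedding table; when None
        the deterministic hashed fallback is used.
    """

    def __init__(self, dimension: int = DEFAULT_DIMENSION, radii=DEFAULT_RADII,
                 seed: int = 42, table_path=None):
        self.dimension = dimension
        self.radii = radii
        self.seed = seed
        self.table_path = table_path

    def fit(self, X=None, y=None):
        if self.table_path is not None:
            self.table_ = load_embedding_table(self.table_path)
        else:
            self.table_ = hashed_embedding_table(self.dimension, self.seed)
        self.dimension_ = self.table_.dimension
        return self

    def _check_fitted(self):
        if not hasattr(self, "table_"):
            self.fit()

    def transform(self, X) -> np.ndarray:
        """X: sequence of SMILES strings → (n, dimension) feature matrix."""
        self._check_fitted()
        rows = [embed_compound(substructure_sentence(s, self.radii), self.table_) for s in X]
        if not rows:
            return np.zeros((0, self.dimension_))
        return np.vstack(rows)

    def provenance(self) -> dict:
        self._check_fitted()
        prov = dict(self.table_.provenance())
        prov["radii"] = list(self.radii)
        if self.table_path is not None:
            prov["table_path"] = str(self.table_path)
        return prov


def featurize_smiles(smiles_list, dimension: int = DEFAULT_DIMENSION,
                     radii=DEFAULT_RADII, seed: int = 42) -> np.ndarray:
    """One-call convenience wrapper over :class:`Mol2VecFeaturizer`."""
    return Mol2VecFeaturizer(dimension=dimension, radii=radii, seed=seed).fit().transform(smiles_list)
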