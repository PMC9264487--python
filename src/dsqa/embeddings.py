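"""Word-embedding tables in the plain-text (GloVe-convention) format.

Each line of an embedding file is a token followed by D decimal numbers,
space-separated.  The production vectors in this problem family are cased
300-dimensional GloVe vectors; lookups therefore try the surface form first
and fall back to the lowercase form before applying the out-of-vocabulary
policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddingTable:
    """token -> vector map with a deterministic out-of-vocabulary policy.

    ``oov_policy`` is ``"zeros"`` (default: unknown tokens map to the zero
    vector) or ``"seeded-random"`` (a vector drawn from a hash-seeded normal
    distribution, identical across calls and processes).
    """

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    oov_policy: str = "zeros"

    def __post_init__(self) -> None:
        if self.oov_policy not in ("zeros", "seeded-random"):
            raise EmbeddingError(f"unknown oov_policy {self.oov_policy!r}")
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise EmbeddingError(
                    f"vector for {tok!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )

    def __contains__(self, token: str) -> bool:
        return token in self.vectors or token.lower() in self.vectors

    def _oov(self, token: str) -> np.ndarray:
        if self.oov_policy == "zeros":
            return np.zeros(self.dimension)
        seed = abs(hash_token(token)) % (2**31)
        return np.random.RandomState(seed).normal(0.0, 0.1, self.dimension)

    def lookup(self, token: str) -> np.ndarray:
        """Vector for ``token``: exact-case hit, then lowercase, then OOV policy."""
        vec = self.vectors.get(token)
        if vec is None:
            vec = self.vectors.get(token.lower())
        if vec is None:
            vec = self._oov(token)
        return vec

    def mean_vector(self, tokens: list[str]) -> np.ndarray:
        """Mean of token vectors; zero vector for an empty token list."""
        if not tokens:
            return np.zeros(self.dimension)
        return np.mean([self.lookup(t) for t in tokens], axis=0)


def hash_token(token: str) -> int:
    """Stable (process-independent) FNV-1a hash of a token."""
    h = 2166136261
    for byte in token.encode("utf-8"):
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h


def load_word_vectors(path, dimension: int) -> EmbeddingTable:
    """Parse a plain-text word-vector file.

    Duplicate tokens keep their first occurrence; a line whose field count
    does not match ``dimension`` + 1 raises with its line number.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dimension + 1:
                raise EmbeddingError(
                    f"line {lineno}: expected token + {dimension} values, "
                    f"got {len(parts)} fields"
                )
            token = parts[0]
            if token in vectors:
                continue
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise EmbeddingError(f"line {lineno}: non-numeric value: {exc}")
            vectors[token] = vec
    return EmbeddingTable(dimension=dimension, vectors=vectors)


def save_word_vectors(table: EmbeddingTable, path) -> None:
    """Write a table back to the plain-text format (one token per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for token in sorted(table.vectors):
            vals = " ".join(repr(float(v)) for v in table.vectors[token])
            fh.write(f"{token} {vals}\n")


def random_embeddings(vocab, dimension: int, seed: int) -> EmbeddingTable:
    """A seeded random table over ``vocab`` (used with synthetic corpora).

    Vectors are unit-normal draws scaled by 1/sqrt(D), giving roughly
    unit-norm, near-orthogonal vectors — a stand-in with the geometry that
    distributional embeddings provide for distinct content words.
    """
    rng = np.random.RandomState(seed)
    vecs: dict[str, np.ndarray] = {}
    for token in sorted(set(vocab)):
        vecs[token] = rng.normal(0.0, 1.0 / np.sqrt(dimension), dimension)
    return EmbeddingTable(dimension=dimension, vectors=vecs)
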