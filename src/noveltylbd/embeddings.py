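"""Fixed-dimension embedding stores for concepts (CUIs) and predicates.

Concept similarity uses cui2vec-style vectors keyed by CUI; predicate
similarity uses word-embedding vectors (GloVe-style) keyed by lower-case
words.  Both are read from the word2vec text format: one key per line
followed by the vector components, with an optional ``<count> <dim>`` header
line that is auto-detected.
"""

from __future__ import annotations

import logging
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "EmbeddingKind",
    "EmbeddingStore",
    "MissingEmbeddingError",
    "EmbeddingFormatError",
    "load_embeddings",
    "save_embeddings",
    "cosine",
    "predicate_vector",
]

logger = logging.getLogger(__name__)


class EmbeddingKind(str, Enum):
    CONCEPT = "concept"
    PREDICATE = "predicate"


class MissingEmbeddingError(KeyError):
    """No vector is resolvable for the requested key."""


class EmbeddingFormatError(ValueError):
    """An embedding file line violated the word2vec text format."""


class EmbeddingStore:
    """A key -> fixed-dimension real vector map.

    Zero vectors are rejected at insertion: they have no direction, so cosine
    similarity against them is undefined.
    """

    def __init__(self, dimension: int, kind: EmbeddingKind):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = int(dimension)
        self.kind = EmbeddingKind(kind)
        self._vectors: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, key: str) -> bool:
        return key in self._vectors

    def keys(self):
        return self._vectors.keys()

    def add(self, key: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.dimension,):
            raise EmbeddingFormatError(
                f"vector for {key!r} has {vector.size} components, expected {self.dimension}"
            )
        if not np.any(vector):
            raise EmbeddingFormatError(f"all-zero vector for key {key!r} rejected")
        if key in self._vectors:
            logger.warning("duplicate embedding key %r: last occurrence wins", key)
        self._vectors[key] = vector

    def get(self, key: str) -> np.ndarray:
        try:
            return self._vectors[key]
        except KeyError:
            raise MissingEmbeddingError(key) from None

    @classmethod
    def from_dict(
        cls, vectors: Mapping[str, np.ndarray], kind: EmbeddingKind
    ) -> "EmbeddingStore":
        it = iter(vectors.items())
        try:
            first_key, first_vec = next(it)
        except StopIteration:
            raise ValueError("cannot infer dimension from an empty mapping") from None
        store = cls(dimension=len(np.asarray(first_vec)), kind=kind)
        store.add(first_key, first_vec)
        for key, vec in it:
            store.add(key, vec)
        return store


def load_embeddings(path: str | Path, kind: EmbeddingKind) -> EmbeddingStore:
    """Read a word2vec-text-format embedding file.

    The first token of each line is the key, the rest are the components.  A
    first line of exactly two integer tokens is treated as the optional
    ``<count> <dimension>`` header.
    """
    path = Path(path)
    store: EmbeddingStore | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if lineno == 1 and len(tokens) == 2:
                try:
                    int(tokens[0]), int(tokens[1])
                    continue  # word2vec count/dim header
                except ValueError:
                    pass
            key, *components = tokens
            try:
                vector = np.array([float(c) for c in components], dtype=np.float64)
            except ValueError as exc:
                raise EmbeddingFormatError(
                    f"line {lineno}: non-numeric component for key {key!r}: {exc}"
                ) from exc
            if store is None:
                store = EmbeddingStore(dimension=vector.size, kind=kind)
            if vector.size != store.dimension:
                raise EmbeddingFormatError(
                    f"line {lineno}: key {key!r} has {vector.size} components, "
                    f"expected {store.dimension}"
                )
            try:
                store.add(key, vector)
            except EmbeddingFormatError as exc:
                raise EmbeddingFormatError(f"line {lineno}: {exc}") from exc
    if store is None:
        raise EmbeddingFormatError(f"empty embedding file: {path}")
    return store


def save_embeddings(store: EmbeddingStore, path: str | Path, header: bool = True) -> None:
    """Write a store in word2vec text format (repr precision, round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(store)} {store.dimension}\n")
        for key in store.keys():
            vec = store.get(key)
            fh.write(key + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u, v) / (||u|| ||v||), in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1 or u.size == 0:
        raise ValueError("cosine requires two 1-d vectors of equal nonzero length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine is undefined for zero-norm vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def predicate_vector(store: EmbeddingStore, predicate: str) -> np.ndarray:
    """Resolve a SemRep-style predicate (e.g. ``PROCESS_OF``) to a vector.

    Direct lookup first; otherwise the predicate is split on underscores,
    lower-cased, and the mean of the word vectors of the tokens present in
    the store is returned (standard bag-of-words composition).
    """
    if store.kind is not EmbeddingKind.PREDICATE:
        raise ValueError("predicate_vector requires a predicate store")
    if predicate in store:
        return store.get(predicate)
    tokens = [t for t in predicate.lower().split("_") if t]
    present = [store.get(t) for t in tokens if t in store]
    if not present:
        raise MissingEmbeddingError(
            f"no embedding for predicate {predicate!r} or any of its tokens"
        )
    return np.mean(present, axis=0)
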