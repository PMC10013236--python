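"""Full-text features for the feature-based importance classifier.

Three feature families are drawn from an article's full text: the section a
triple appeared in (always available), the TextRank score of the triple's
sentence (available only when sentence text is extractable), and the depths
of the two CUIs in a concept hierarchy (available only when both CUIs occur
in the hierarchy).  Absences are first-class: the *availability pattern* of a
feature vector indexes which trained model applies to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .triples import Predication

__all__ = [
    "FeatureVector",
    "compute_textrank",
    "tokenize_sentence",
    "ConceptHierarchy",
    "load_hierarchy",
    "extract_features",
]

TEXTRANK_DAMPING = 0.85
TEXTRANK_TOL = 1e-6
TEXTRANK_MAX_ITER = 100


@dataclass(frozen=True)
class FeatureVector:
    """Features of one predication; ``None`` marks an unavailable feature."""

    section_name: str
    textrank: Optional[float] = None
    subject_depth: Optional[int] = None
    object_depth: Optional[int] = None

    @property
    def availability_pattern(self) -> tuple[str, ...]:
        """Sorted names of the optional features that are present."""
        present = []
        if self.textrank is not None:
            present.append("textrank")
        if self.subject_depth is not None:
            present.append("subject_depth")
        if self.object_depth is not None:
            present.append("object_depth")
        return tuple(sorted(present))


def tokenize_sentence(text: str) -> list[str]:
    """Lower-cased alphanumeric word split (TextRank preprocessing)."""
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def _sentence_similarity(s1: Sequence[str], s2: Sequence[str]) -> float:
    """Token overlap normalised by log sentence lengths."""
    if not s1 or not s2:
        return 0.0
    overlap = len(set(s1) & set(s2))
    denom = math.log(len(s1)) + math.log(len(s2))
    if denom <= 0.0:
        return 0.0
    return overlap / denom


def compute_textrank(sentences: Sequence[Sequence[str]]) -> dict[int, float]:
    """TextRank scores of sentences, as a map sentence_index -> score.

    Builds the undirected sentence graph weighted by normalised token
    overlap and runs damped power iteration (damping 0.85, tolerance 1e-6,
    at most 100 iterations).  Scores are normalised to sum to 1.
    """
    n = len(sentences)
    if n == 0:
        raise ValueError("at least one sentence is required")
    if n == 1:
        return {0: 1.0}
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w = _sentence_similarity(sentences[i], sentences[j])
            W[i, j] = W[j, i] = w
    out_weight = W.sum(axis=1)
    scores = np.full(n, 1.0 / n)
    d = TEXTRANK_DAMPING
    for _ in range(TEXTRANK_MAX_ITER):
        new = np.full(n, (1.0 - d) / n)
        for j in range(n):
            if out_weight[j] > 0.0:
                new += d * scores[j] * W[j] / out_weight[j]
        if np.abs(new - scores).sum() < TEXTRANK_TOL:
            scores = new
            break
        scores = new
    scores = scores / scores.sum()
    return {i: float(scores[i]) for i in range(n)}


class ConceptHierarchy:
    """A rooted tree (or forest) over concepts, for the CUI-depth feature.

    Depth is the path length from the root of a concept's tree: roots have
    depth 0.  Concepts absent from the hierarchy have no depth, and the
    corresponding feature is simply unavailable.
    """

    def __init__(self, parent_of: Mapping[str, str]):
        self._parent = dict(parent_of)
        # cycle check while memoising depths
        self._depth: dict[str, int] = {}
        for node in list(self._parent) + list(self._parent.values()):
            self.depth(node)

    def __contains__(self, cui: str) -> bool:
        return cui in self._depth

    def depth(self, cui: str) -> int:
        if cui in self._depth:
            return self._depth[cui]
        chain = []
        node = cui
        while node in self._parent and node not in self._depth:
            if node in chain:
                raise ValueError(f"cycle in hierarchy at {node!r}")
            chain.append(node)
            node = self._parent[node]
        base = self._depth.get(node, 0)
        self._depth.setdefault(node, base)
        for i, n in enumerate(reversed(chain), start=1):
            self._depth[n] = base + i
        return self._depth[cui]

    def get_depth(self, cui: str) -> Optional[int]:
        return self._depth.get(cui)


def load_hierarchy(path: str | Path) -> ConceptHierarchy:
    """Read a parent-child TSV file (``parent<TAB>child`` per line)."""
    parent_of: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'parent<TAB>child'")
            parent, child = parts
            parent_of[child] = parent
    return ConceptHierarchy(parent_of)


def extract_features(
    predication: Predication,
    hierarchy: Optional[ConceptHierarchy] = None,
    textrank_scores: Optional[Mapping[int, float]] = None,
) -> FeatureVector:
    """Build the feature vector of one predication.

    ``textrank_scores`` is the per-document sentence-index -> TextRank map
    (from :func:`compute_textrank` over the document's sentences); the
    textrank feature is present only when the predication has a sentence
    index covered by that map.  Depths are present only for CUIs that occur
    in the hierarchy.
    """
    textrank = None
    if textrank_scores is not None and predication.sentence_index is not None:
        textrank = textrank_scores.get(predication.sentence_index)
    subject_depth = object_depth = None
    if hierarchy is not None:
        subject_depth = hierarchy.get_depth(predication.triple.subject_cui)
        object_depth = hierarchy.get_depth(predication.triple.object_cui)
    return FeatureVector(
        section_name=predication.section.value,
        textrank=textrank,
        subject_depth=subject_depth,
        object_depth=object_depth,
    )
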