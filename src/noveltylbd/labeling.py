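"""Triple similarity and the importance-labelled training set.

The working hypothesis is that a paper's novel contribution is stated both in
its abstract and in its body.  A body triple's *importance score* is its
maximum similarity to any abstract triple of the same document, where the
similarity of two triples cui11-rel1-cui12 and cui21-rel2-cui22 is the sum of
three cosine similarities — subject vs subject and object vs object under the
concept embeddings, predicate vs predicate under the word embeddings — giving
a value in [0, 3].

Thresholding that score with a gap yields the binary training set:
score >= 2.5 -> important, score <= 1.5 -> not important, scores inside the
gap are discarded so the two classes are well separated.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .embeddings import (
    EmbeddingStore,
    MissingEmbeddingError,
    cosine,
    predicate_vector,
)
from .triples import Corpus, Predication, Section, Triple, distinct_triples

__all__ = [
    "ImportanceLabel",
    "SimilarityConfig",
    "LabeledTriple",
    "LabelingResult",
    "NoAbstractTriplesError",
    "triple_similarity",
    "max_abstract_similarity",
    "build_training_set",
    "balance_by_undersampling",
    "write_labeled",
    "read_labeled",
]

logger = logging.getLogger(__name__)


class ImportanceLabel(str, Enum):
    IMPORTANT = "important"
    NOT_IMPORTANT = "not_important"
    DISCARDED_GAP = "discarded_gap"


class NoAbstractTriplesError(ValueError):
    """The document has no abstract triples, so body scores are undefined."""


@dataclass(frozen=True)
class SimilarityConfig:
    """Thresholds for the similarity gap and cosine clamping.

    ``hi``/``lo`` are the important / not-important thresholds (scores in the
    open gap between them are discarded).  With ``clamp_negative_cosines`` on,
    each of the three cosines is clamped to max(0, cos) so the triple
    similarity lies in [0, 3] exactly; raw mode keeps negative cosines and the
    range becomes [-3, 3].
    """

    hi: float = 2.5
    lo: float = 1.5
    clamp_negative_cosines: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 3.0):
            raise ValueError(f"thresholds must satisfy 0 <= lo < hi <= 3, got lo={self.lo} hi={self.hi}")

    def label_for_score(self, score: float) -> ImportanceLabel:
        if score >= self.hi:
            return ImportanceLabel.IMPORTANT
        if score <= self.lo:
            return ImportanceLabel.NOT_IMPORTANT
        return ImportanceLabel.DISCARDED_GAP


@dataclass(frozen=True)
class LabeledTriple:
    """A body predication with its importance score and binary label."""

    predication: Predication
    score: float
    label: ImportanceLabel
    # arg-max abstract triple, kept for explainability
    best_abstract_triple: Optional[Triple] = None


@dataclass
class LabelingResult:
    """Labelled triples plus bookkeeping on skipped items."""

    labeled: list[LabeledTriple] = field(default_factory=list)
    docs_without_abstract: int = 0
    skipped_missing_embedding: int = 0

    def by_label(self, label: ImportanceLabel) -> list[LabeledTriple]:
        return [lt for lt in self.labeled if lt.label is label]

    def training_instances(self) -> list[LabeledTriple]:
        """Important and not-important instances; gap instances excluded."""
        return [lt for lt in self.labeled if lt.label is not ImportanceLabel.DISCARDED_GAP]


def _clamp(x: float, enabled: bool) -> float:
    return max(0.0, x) if enabled else x


def triple_similarity(
    t1: Triple,
    t2: Triple,
    concepts: EmbeddingStore,
    predicates: EmbeddingStore,
    config: SimilarityConfig = SimilarityConfig(),
) -> float:
    """Three-way cosine-sum similarity of two triples, symmetric in (t1, t2)."""
    c = config.clamp_negative_cosines
    s = _clamp(cosine(concepts.get(t1.subject_cui), concepts.get(t2.subject_cui)), c)
    p = _clamp(
        cosine(predicate_vector(predicates, t1.predicate), predicate_vector(predicates, t2.predicate)),
        c,
    )
    o = _clamp(cosine(concepts.get(t1.object_cui), concepts.get(t2.object_cui)), c)
    return s + p + o


def max_abstract_similarity(
    body: Predication | Triple,
    abstract_triples: Iterable[Triple],
    concepts: EmbeddingStore,
    predicates: EmbeddingStore,
    config: SimilarityConfig = SimilarityConfig(),
) -> tuple[float, Triple]:
    """Maximum similarity of a body triple to any abstract triple.

    Returns ``(score, argmax_abstract_triple)``.  Raises
    :class:`NoAbstractTriplesError` on an empty abstract set and
    :class:`MissingEmbeddingError` if the body triple itself is unresolvable;
    abstract triples with unresolvable embeddings are skipped.
    """
    triple = body.triple if isinstance(body, Predication) else body
    best: Optional[tuple[float, Triple]] = None
    empty = True
    for at in abstract_triples:
        empty = False
        try:
            score = triple_similarity(triple, at, concepts, predicates, config)
        except MissingEmbeddingError:
            # unresolvable *abstract* triple: skip the pair, not the body triple
            continue
        if best is None or score > best[0]:
            best = (score, at)
    if empty:
        raise NoAbstractTriplesError("document has no abstract triples")
    if best is None:
        raise MissingEmbeddingError("no abstract triple was resolvable in the stores")
    return best


def build_training_set(
    corpus: Corpus,
    concepts: EmbeddingStore,
    predicates: EmbeddingStore,
    config: SimilarityConfig = SimilarityConfig(),
) -> LabelingResult:
    """Score and label every body predication of every eligible document.

    Documents with no abstract triples are skipped (counted); body triples
    whose embeddings cannot be resolved are skipped (counted), never silently
    scored 0.  Gap instances are retained with label ``discarded_gap`` but
    excluded from :meth:`LabelingResult.training_instances`.
    """
    result = LabelingResult()
    by_doc: dict[str, list[Predication]] = {}
    for p in corpus:
        by_doc.setdefault(p.doc_id, []).append(p)
    for doc_id, preds in by_doc.items():
        abstract = distinct_triples(p for p in preds if p.section is Section.ABSTRACT)
        body = [p for p in preds if p.section is Section.BODY]
        if not body:
            continue
        if not abstract:
            result.docs_without_abstract += 1
            continue
        for p in body:
            try:
                score, best = max_abstract_similarity(
                    p, abstract, concepts, predicates, config
                )
            except MissingEmbeddingError:
                result.skipped_missing_embedding += 1
                continue
            result.labeled.append(
                LabeledTriple(
                    predication=p,
                    score=score,
                    label=config.label_for_score(score),
                    best_abstract_triple=best,
                )
            )
    return result


def balance_by_undersampling(
    labeled: Iterable[LabeledTriple], seed: int
) -> list[LabeledTriple]:
    """Randomly under-sample the majority class to equal class sizes.

    Gap instances are dropped.  The minority class is untouched; sampling is
    reproducible for a fixed seed.
    """
    important = [lt for lt in labeled if lt.label is ImportanceLabel.IMPORTANT]
    not_important = [lt for lt in labeled if lt.label is ImportanceLabel.NOT_IMPORTANT]
    if not important or not not_important:
        raise ValueError("both classes must be non-empty before balancing")
    rng = np.random.default_rng(seed)
    n = min(len(important), len(not_important))

    def sample(items: list[LabeledTriple]) -> list[LabeledTriple]:
        if len(items) == n:
            return list(items)
        idx = rng.choice(len(items), size=n, replace=False)
        return [items[i] for i in sorted(idx)]

    return sample(important) + sample(not_important)


_LABELED_HEADER = [
    "doc_id", "date", "section", "sentence_index", "sentence_text",
    "subject_cui", "predicate", "object_cui", "score", "label",
]


def write_labeled(labeled: Iterable[LabeledTriple], path: str | Path) -> None:
    """Export labelled triples as TSV (predication columns + score + label)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LABELED_HEADER)
        for lt in labeled:
            p = lt.predication
            writer.writerow([
                p.doc_id, p.date.isoformat(), p.section.value,
                "-" if p.sentence_index is None else p.sentence_index,
                "-" if p.sentence_text is None else p.sentence_text,
                p.triple.subject_cui, p.triple.predicate, p.triple.object_cui,
                repr(float(lt.score)), lt.label.value,
            ])


def read_labeled(path: str | Path) -> list[LabeledTriple]:
    """Read a labelled-triple TSV written by :func:`write_labeled`."""
    import datetime as _dt

    out: list[LabeledTriple] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _LABELED_HEADER:
            raise ValueError(f"unexpected labelled-set header: {header}")
        for row in reader:
            (doc_id, date_s, section, sidx, stext, subj, pred, obj, score, label) = row
            out.append(
                LabeledTriple(
                    predication=Predication(
                        doc_id=doc_id,
                        date=_dt.date.fromisoformat(date_s),
                        section=Section(section),
                        triple=Triple(subj, pred, obj),
                        sentence_index=None if sidx == "-" else int(sidx),
                        sentence_text=None if stext == "-" else stext,
                    ),
                    score=float(score),
                    label=ImportanceLabel(label),
                )
            )
    return out
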