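"""Synthetic corpora with planted importance and hidden-knowledge structure.

Emulates, at desk scale, the corpus features the pipeline relies on:

* every document's *novel contribution* triples appear in both its abstract
  and its body (each uses a pair of concepts unique to that document, so
  novel triples never chain into spurious two-step paths);
* *background knowledge* triples appear in bodies only, in most documents
  (high document frequency), and are built around a shared generic hub
  concept — the "patient"-like term through which background relations chain;
* *hidden knowledge* is planted as chains (A, B, C): A->B and B->C are
  published before the cutoff date, A->C appears on or after it, so open
  discovery on the pre-cutoff slice should propose exactly the (A, C) pairs;
* embeddings are unit vectors with background concepts/predicates confined
  to a subspace orthogonal to the novel/planted subspace, so similarity
  labels are separable *by construction*: copied novel triples score 3,
  background triples score 0 against any abstract.

Generation is a pure function of the spec (including its seed): rerunning
with the same spec yields byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .embeddings import EmbeddingKind, EmbeddingStore
from .features import ConceptHierarchy, FeatureVector
from .triples import Corpus, Predication, Section, Triple

__all__ = [
    "SyntheticSpec",
    "gen_embeddings",
    "gen_corpus",
    "gen_hierarchy",
    "gen_feature_training_data",
    "planted_pairs",
]

NOVEL_PREDICATES = ("TREATS", "CAUSES", "PREVENTS", "INHIBITS")
BACKGROUND_PREDICATES = ("ISA", "PROCESS_OF", "LOCATION_OF", "PART_OF")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``background_pool`` distinct body-only background triples are built
    around one hub concept; ``planted_hidden`` chains may be given
    explicitly as (A, B, C) CUI triples, otherwise ``n_planted_chains``
    fresh chains are created.  ``noise_rate`` is the per-document
    probability of each extra random background-style body triple;
    ``gap_per_doc`` body triples per document are constructed to land inside
    the similarity gap (same concepts as an abstract triple, background
    predicate — score 2), exercising the discard logic.
    """

    n_docs: int = 40
    cutoff: _dt.date = _dt.date(2021, 1, 1)
    n_concepts: Optional[int] = None  # None: exactly as many as needed
    embedding_dim: int = 8
    novel_per_doc: int = 2
    background_pool: int = 10
    planted_hidden: Optional[tuple[tuple[str, str, str], ...]] = None
    n_planted_chains: int = 3
    noise_rate: float = 0.0
    gap_per_doc: int = 0
    seed: int = 0
    pre_window_start: _dt.date = _dt.date(2020, 1, 1)
    post_window_end: _dt.date = _dt.date(2021, 6, 13)

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.background_pool < 2:
            raise ValueError("background_pool must be >= 2 for chaining structure")
        if self.n_docs < 2:
            raise ValueError("need at least one pre and one post document")


def _cui(i: int) -> str:
    return f"C{i:07d}"


@dataclass
class _Layout:
    """Deterministic concept allocation shared by all generators."""

    hub: str
    spokes: list[str]
    chains: list[tuple[str, str, str]]
    novel_pairs: list[list[tuple[str, str]]]  # per document
    background_triples: list[Triple]
    all_concepts: list[str]
    background_concepts: set[str]


def _layout(spec: SyntheticSpec) -> _Layout:
    counter = 1
    hub = _cui(counter)
    counter += 1
    spokes = []
    for _ in range(spec.background_pool):
        spokes.append(_cui(counter))
        counter += 1
    if spec.planted_hidden is not None:
        chains = [tuple(c) for c in spec.planted_hidden]
        planted_concepts = [c for chain in chains for c in chain]
    else:
        chains = []
        planted_concepts = []
        for _ in range(spec.n_planted_chains):
            a, b, c = _cui(counter), _cui(counter + 1), _cui(counter + 2)
            counter += 3
            chains.append((a, b, c))
            planted_concepts.extend((a, b, c))
    novel_pairs: list[list[tuple[str, str]]] = []
    for _ in range(spec.n_docs):
        pairs = []
        for _ in range(spec.novel_per_doc):
            pairs.append((_cui(counter), _cui(counter + 1)))
            counter += 2
        novel_pairs.append(pairs)
    # background triples chain through the hub: spoke -> hub and hub -> spoke
    background_triples = []
    for k, spoke in enumerate(spokes):
        pred = BACKGROUND_PREDICATES[k % len(BACKGROUND_PREDICATES)]
        if k % 2 == 0:
            background_triples.append(Triple(spoke, pred, hub))
        else:
            background_triples.append(Triple(hub, pred, spoke))
    all_concepts = sorted(
        {hub, *spokes, *planted_concepts}
        | {c for pairs in novel_pairs for pair in pairs for c in pair}
    )
    if spec.n_concepts is not None and spec.n_concepts < len(all_concepts):
        raise ValueError(
            f"spec inconsistent: needs {len(all_concepts)} concepts, "
            f"n_concepts={spec.n_concepts}"
        )
    return _Layout(
        hub=hub,
        spokes=spokes,
        chains=chains,
        novel_pairs=novel_pairs,
        background_triples=background_triples,
        all_concepts=all_concepts,
        background_concepts={hub, *spokes},
    )


def _subspace_unit(rng: np.random.Generator, dim: int, lo: int, hi: int) -> np.ndarray:
    v = np.zeros(dim)
    while True:
        v[lo:hi] = rng.normal(size=hi - lo)
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            return v / norm


def gen_embeddings(spec: SyntheticSpec) -> tuple[EmbeddingStore, EmbeddingStore]:
    """Unit-norm concept and predicate stores with orthogonal class subspaces.

    Background concepts/predicates live in the first half of the embedding
    dimensions; novel and planted ones in the second half, so every
    background-vs-novel cosine is exactly 0.
    """
    layout = _layout(spec)
    rng = np.random.default_rng(spec.seed + 2)
    d = spec.embedding_dim
    half = d // 2
    concepts = EmbeddingStore(dimension=d, kind=EmbeddingKind.CONCEPT)
    for cui in layout.all_concepts:
        if cui in layout.background_concepts:
            concepts.add(cui, _subspace_unit(rng, d, 0, half))
        else:
            concepts.add(cui, _subspace_unit(rng, d, half, d))
    predicates = EmbeddingStore(dimension=d, kind=EmbeddingKind.PREDICATE)
    for pred in BACKGROUND_PREDICATES:
        predicates.add(pred, _subspace_unit(rng, d, 0, half))
    for pred in NOVEL_PREDICATES:
        predicates.add(pred, _subspace_unit(rng, d, half, d))
    return concepts, predicates


def _random_date(rng: np.random.Generator, start: _dt.date, end_exclusive: _dt.date) -> _dt.date:
    span = (end_exclusive - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span)))


def gen_corpus(spec: SyntheticSpec) -> Corpus:
    """Generate the dated, sectioned corpus with the planted structure."""
    layout = _layout(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n_pre = spec.n_docs // 2
    n_post = spec.n_docs - n_pre
    novel_pred = [NOVEL_PREDICATES[i % len(NOVEL_PREDICATES)] for i in range(spec.novel_per_doc)]

    # assign planted relations to documents round-robin
    pre_planted: dict[int, list[Triple]] = {}
    post_planted: dict[int, list[Triple]] = {}
    for j, (a, b, c) in enumerate(layout.chains):
        pred = NOVEL_PREDICATES[j % len(NOVEL_PREDICATES)]
        pre_planted.setdefault(j % n_pre, []).append(Triple(a, pred, b))
        pre_planted.setdefault((j + 1) % n_pre, []).append(Triple(b, pred, c))
        post_planted.setdefault(j % n_post, []).append(Triple(a, pred, c))

    predications: list[Predication] = []
    for doc_index in range(spec.n_docs):
        is_pre = doc_index < n_pre
        doc_id = f"DOC{doc_index:05d}"
        if is_pre:
            date = _random_date(rng, spec.pre_window_start, spec.cutoff)
            planted = pre_planted.get(doc_index, [])
        else:
            date = _random_date(
                rng, spec.cutoff, spec.post_window_end + _dt.timedelta(days=1)
            )
            planted = post_planted.get(doc_index - n_pre, [])
        novel = [
            Triple(s, novel_pred[i], o)
            for i, (s, o) in enumerate(layout.novel_pairs[doc_index])
        ]
        abstract_triples = novel + planted
        body_triples = list(abstract_triples) + list(layout.background_triples)
        # gap triples: same concepts as an abstract triple, background predicate
        for g in range(min(spec.gap_per_doc, len(abstract_triples))):
            src = abstract_triples[g]
            body_triples.append(
                Triple(src.subject_cui, BACKGROUND_PREDICATES[g % len(BACKGROUND_PREDICATES)],
                       src.object_cui)
            )
        # noise: extra random background-style body triples
        if spec.noise_rate > 0.0:
            for k in range(spec.background_pool):
                if rng.random() < spec.noise_rate:
                    i, j = rng.choice(len(layout.spokes), size=2, replace=False)
                    body_triples.append(
                        Triple(
                            layout.spokes[int(i)],
                            BACKGROUND_PREDICATES[int(rng.integers(len(BACKGROUND_PREDICATES)))],
                            layout.spokes[int(j)],
                        )
                    )
        sentence = 0
        for t in abstract_triples:
            predications.append(
                Predication(doc_id=doc_id, date=date, section=Section.ABSTRACT,
                            triple=t, sentence_index=sentence, sentence_text=str(t))
            )
            sentence += 1
        for t in body_triples:
            predications.append(
                Predication(doc_id=doc_id, date=date, section=Section.BODY,
                            triple=t, sentence_index=sentence, sentence_text=str(t))
            )
            sentence += 1
    return Corpus(predications)


def gen_hierarchy(spec: SyntheticSpec) -> ConceptHierarchy:
    """A random recursive rooted tree over the concept set (depth feature)."""
    layout = _layout(spec)
    rng = np.random.default_rng(spec.seed + 3)
    concepts = layout.all_concepts
    parent_of: dict[str, str] = {}
    for i in range(1, len(concepts)):
        parent_of[concepts[i]] = concepts[int(rng.integers(0, i))]
    return ConceptHierarchy(parent_of)


def planted_pairs(spec: SyntheticSpec) -> set[tuple[str, str]]:
    """The hidden (A, C) pairs the generator plants across the cutoff."""
    return {(a, c) for a, _, c in _layout(spec).chains}


def gen_feature_training_data(
    n_per_class: int = 500,
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> list[tuple[FeatureVector, int]]:
    """Two separable Gaussian blobs in (textrank, subject_depth, object_depth).

    Important triples sit at high TextRank / shallow concepts, unimportant
    ones at low TextRank / deep generic concepts — the direction the real
    features are hypothesised to discriminate in.  ``missing_fraction`` of
    instances lose their depth features, producing a second availability
    pattern for the missing-feature model-selection logic.
    """
    rng = np.random.default_rng(seed)
    data: list[tuple[FeatureVector, int]] = []
    for label, tr_mean, depth_mean in ((1, 0.8, 2.0), (0, 0.15, 9.0)):
        for _ in range(n_per_class):
            textrank = max(0.0, rng.normal(tr_mean, 0.08))
            sd = max(0, int(round(rng.normal(depth_mean, 1.0))))
            od = max(0, int(round(rng.normal(depth_mean, 1.0))))
            if rng.random() < missing_fraction:
                fv = FeatureVector(section_name="body", textrank=textrank)
            else:
                fv = FeatureVector(section_name="body", textrank=textrank,
                                   subject_depth=sd, object_depth=od)
            data.append((fv, label))
    return data
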