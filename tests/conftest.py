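import datetime as dt

import numpy as np
import pytest

from noveltylbd.embeddings import EmbeddingKind, EmbeddingStore
from noveltylbd.triples import Corpus, Predication, Section, Triple


def make_predication(
    triple: Triple,
    doc_id: str = "DOC1",
    date: dt.date = dt.date(2020, 6, 1),
    section: Section = Section.BODY,
    sentence_index=None,
    sentence_text=None,
) -> Predication:
    return Predication(
        doc_id=doc_id, date=date, section=section, triple=triple,
        sentence_index=sentence_index, sentence_text=sentence_text,
    )


@pytest.fixture
def random_stores():
    """Seeded random 10-dim concept and predicate stores over generic keys."""
    rng = np.random.default_rng(42)
    concepts = EmbeddingStore(dimension=10, kind=EmbeddingKind.CONCEPT)
    for i in range(20):
        concepts.add(f"C{i:07d}", rng.normal(size=10))
    predicates = EmbeddingStore(dimension=10, kind=EmbeddingKind.PREDICATE)
    for name in ("TREATS", "CAUSES", "ISA", "PROCESS_OF", "INHIBITS"):
        predicates.add(name, rng.normal(size=10))
    return concepts, predicates


@pytest.fixture
def exact_cosine_stores():
    """Stores engineered so every pairwise cosine is exactly 1.0, 0.5 or 0.0.

    e1 = (1,0,0,0) and ones = (1,1,1,1) have dot 1 and norms 1 and 2, so
    their cosine is exactly 0.5 in floating point; orthogonal unit axes give
    exactly 0.  Triple scores built from these are exact sums like 2.5.
    """
    e1 = np.array([1.0, 0.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0, 0.0])
    ones = np.array([1.0, 1.0, 1.0, 1.0])
    concepts = EmbeddingStore.from_dict(
        {"CSUBJ": e1, "CSUBJ2": ones, "CSUBJX": e2,
         "COBJ": e1, "COBJ2": ones, "COBJX": e2},
        kind=EmbeddingKind.CONCEPT,
    )
    predicates = EmbeddingStore.from_dict(
        {"TREATS": e1, "CAUSES": ones, "ISA": e2},
        kind=EmbeddingKind.PREDICATE,
    )
    return concepts, predicates


@pytest.fixture
def toy_corpus():
    """Two documents straddling 2021-01-01 with abstract and body triples."""
    t1 = Triple("C0000001", "TREATS", "C0000002")
    t2 = Triple("C0000003", "CAUSES", "C0000004")
    t3 = Triple("C0000005", "ISA", "C0000006")
    return Corpus([
        make_predication(t1, doc_id="A", date=dt.date(2020, 12, 31),
                         section=Section.ABSTRACT),
        make_predication(t1, doc_id="A", date=dt.date(2020, 12, 31)),
        make_predication(t2, doc_id="A", date=dt.date(2020, 12, 31)),
        make_predication(t3, doc_id="B", date=dt.date(2021, 1, 1),
                         section=Section.ABSTRACT, sentence_index=0,
                         sentence_text="five isa six"),
        make_predication(t2, doc_id="B", date=dt.date(2021, 1, 1)),
    ])
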