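import datetime as dt
import itertools
import math

import numpy as np
import pytest

from noveltylbd.embeddings import EmbeddingKind, EmbeddingStore
from noveltylbd.labeling import (
    ImportanceLabel,
    NoAbstractTriplesError,
    SimilarityConfig,
    balance_by_undersampling,
    build_training_set,
    max_abstract_similarity,
    triple_similarity,
)
from noveltylbd.synthetic import SyntheticSpec, gen_corpus, gen_embeddings
from noveltylbd.triples import Corpus, Section, Triple
from conftest import make_predication


def _plain_cosine(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return dot / (nu * nv)


class TestTripleSimilarity:
    def test_self_similarity_is_three(self, random_stores):
        concepts, predicates = random_stores
        t = Triple("C0000001", "TREATS", "C0000002")
        assert triple_similarity(t, t, concepts, predicates) == pytest.approx(3.0)

    def test_identical_concepts_orthogonal_predicates(self, exact_cosine_stores):
        concepts, predicates = exact_cosine_stores
        t1 = Triple("CSUBJ", "TREATS", "COBJ")   # TREATS = e1
        t2 = Triple("CSUBJ", "ISA", "COBJ")      # ISA = e2, orthogonal
        assert triple_similarity(t1, t2, concepts, predicates) == 2.0

    def test_matches_independent_cosine_sum(self, random_stores):
        concepts, predicates = random_stores
        t1 = Triple("C0000003", "CAUSES", "C0000007")
        t2 = Triple("C0000011", "ISA", "C0000002")
        expected = sum(
            max(0.0, _plain_cosine(u.tolist(), v.tolist()))
            for u, v in [
                (concepts.get("C0000003"), concepts.get("C0000011")),
                (predicates.get("CAUSES"), predicates.get("ISA")),
                (concepts.get("C0000007"), concepts.get("C0000002")),
            ]
        )
        got = triple_similarity(t1, t2, concepts, predicates)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_over_random_pairs(self, random_stores):
        concepts, predicates = random_stores
        cuis = sorted(concepts.keys())[:6]
        preds = sorted(predicates.keys())[:3]
        triples = [Triple(s, p, o) for s, p, o in itertools.product(cuis[:3], preds, cuis[3:])]
        for t1, t2 in itertools.combinations(triples, 2):
            a = triple_similarity(t1, t2, concepts, predicates)
            b = triple_similarity(t2, t1, concepts, predicates)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 3.0

    def test_unclamped_mode_allows_negative_components(self):
        concepts = EmbeddingStore.from_dict(
            {"C1": np.array([1.0, 0.0]), "C2": np.array([-1.0, 0.0])},
            EmbeddingKind.CONCEPT,
        )
        predicates = EmbeddingStore.from_dict(
            {"ISA": np.array([1.0, 0.0])}, EmbeddingKind.PREDICATE
        )
        t1, t2 = Triple("C1", "ISA", "C1"), Triple("C2", "ISA", "C2")
        clamped = triple_similarity(t1, t2, concepts, predicates)
        raw = triple_similarity(
            t1, t2, concepts, predicates, SimilarityConfig(clamp_negative_cosines=False)
        )
        assert clamped == 1.0  # 0 + 1 + 0
        assert raw == -1.0     # -1 + 1 - 1


class TestMaxAbstractSimilarity:
    def test_verbatim_copy_scores_three(self, random_stores):
        concepts, predicates = random_stores
        t = Triple("C0000001", "TREATS", "C0000002")
        score, best = max_abstract_similarity(t, {t}, concepts, predicates)
        assert score == pytest.approx(3.0) and best == t

    def test_equals_brute_force_max_over_pairs(self, random_stores):
        concepts, predicates = random_stores
        rng = np.random.default_rng(5)
        cuis = sorted(concepts.keys())
        preds = sorted(predicates.keys())
        abstract = {
            Triple(cuis[rng.integers(20)], preds[rng.integers(5)], cuis[rng.integers(20)])
            for _ in range(20)
        }
        body = Triple("C0000000", "ISA", "C0000019")
        brute = max(
            triple_similarity(body, at, concepts, predicates) for at in abstract
        )
        score, best = max_abstract_similarity(body, abstract, concepts, predicates)
        assert score == pytest.approx(brute, abs=1e-12)
        assert triple_similarity(body, best, concepts, predicates) == pytest.approx(score)

    def test_empty_abstract_set_raises(self, random_stores):
        concepts, predicates = random_stores
        with pytest.raises(NoAbstractTriplesError):
            max_abstract_similarity(
                Triple("C0000001", "ISA", "C0000002"), set(), concepts, predicates
            )


class TestThresholdSemantics:
    """Boundary labels: score >= 2.5 important, <= 1.5 not, gap discarded."""

    def _corpus(self):
        abstract = Triple("CSUBJ", "TREATS", "COBJ")
        # cosines against the abstract triple (exact fp values):
        score_25 = Triple("CSUBJ", "TREATS", "COBJ2")    # 1 + 1 + 0.5
        score_15 = Triple("CSUBJ2", "CAUSES", "COBJ2")   # 0.5 + 0.5 + 0.5
        score_20 = Triple("CSUBJ", "CAUSES", "COBJ2")    # 1 + 0.5 + 0.5
        preds = [make_predication(abstract, section=Section.ABSTRACT)]
        preds += [make_predication(t) for t in (score_25, score_15, score_20)]
        return Corpus(preds)

    def test_exact_boundary_scores_label_correctly(self, exact_cosine_stores):
        concepts, predicates = exact_cosine_stores
        result = build_training_set(self._corpus(), concepts, predicates)
        by_score = {lt.score: lt.label for lt in result.labeled}
        assert by_score == {
            2.5: ImportanceLabel.IMPORTANT,
            1.5: ImportanceLabel.NOT_IMPORTANT,
            2.0: ImportanceLabel.DISCARDED_GAP,
        }

    def test_gap_instances_excluded_from_training(self, exact_cosine_stores):
        concepts, predicates = exact_cosine_stores
        result = build_training_set(self._corpus(), concepts, predicates)
        assert len(result.labeled) == 3
        assert {lt.score for lt in result.training_instances()} == {2.5, 1.5}

    def test_document_without_abstract_is_skipped_and_counted(self, random_stores):
        concepts, predicates = random_stores
        corpus = Corpus([make_predication(Triple("C0000001", "ISA", "C0000002"))])
        result = build_training_set(corpus, concepts, predicates)
        assert result.labeled == [] and result.docs_without_abstract == 1

    def test_label_is_pure_function_of_score(self):
        config = SimilarityConfig()
        assert config.label_for_score(2.5) is ImportanceLabel.IMPORTANT
        assert config.label_for_score(1.5) is ImportanceLabel.NOT_IMPORTANT
        assert config.label_for_score(2.0) is ImportanceLabel.DISCARDED_GAP
        with pytest.raises(ValueError):
            SimilarityConfig(hi=1.0, lo=2.0)


class TestPlantedSeparability:
    def test_noise_free_corpus_labels_exactly_planted(self):
        spec = SyntheticSpec(n_docs=10, seed=3)
        corpus = gen_corpus(spec)
        concepts, predicates = gen_embeddings(spec)
        result = build_training_set(corpus, concepts, predicates)
        assert result.docs_without_abstract == 0
        assert result.skipped_missing_embedding == 0
        for lt in result.labeled:
            if lt.label is ImportanceLabel.IMPORTANT:
                assert lt.score == pytest.approx(3.0)
            else:
                assert lt.label is ImportanceLabel.NOT_IMPORTANT
                assert lt.score == pytest.approx(0.0, abs=1e-12)


class TestUndersampling:
    def _labeled(self, n_imp, n_not, stores):
        concepts, predicates = stores
        out = []
        from noveltylbd.labeling import LabeledTriple

        for i in range(n_imp):
            out.append(LabeledTriple(
                make_predication(Triple("C0000001", "ISA", "C0000002"), doc_id=f"I{i}"),
                3.0, ImportanceLabel.IMPORTANT))
        for i in range(n_not):
            out.append(LabeledTriple(
                make_predication(Triple("C0000003", "ISA", "C0000004"), doc_id=f"N{i}"),
                0.0, ImportanceLabel.NOT_IMPORTANT))
        return out

    def test_equal_class_sizes_minority_untouched(self, random_stores):
        labeled = self._labeled(10, 40, random_stores)
        balanced = balance_by_undersampling(labeled, seed=0)
        imp = [lt for lt in balanced if lt.label is ImportanceLabel.IMPORTANT]
        not_imp = [lt for lt in balanced if lt.label is ImportanceLabel.NOT_IMPORTANT]
        assert len(imp) == len(not_imp) == 10
        assert imp == labeled[:10]  # minority class untouched

    def test_already_balanced_is_identity(self, random_stores):
        labeled = self._labeled(5, 5, random_stores)
        assert balance_by_undersampling(labeled, seed=1) == labeled

    def test_seed_determinism(self, random_stores):
        labeled = self._labeled(10, 200, random_stores)
        a = balance_by_undersampling(labeled, seed=7)
        b = balance_by_undersampling(labeled, seed=7)
        c = balance_by_undersampling(labeled, seed=8)
        assert a == b
        assert a != c

    def test_empty_class_rejected(self, random_stores):
        labeled = self._labeled(5, 0, random_stores)
        with pytest.raises(ValueError):
            balance_by_undersampling(labeled, seed=0)
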