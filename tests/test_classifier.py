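import numpy as np
import pytest

from noveltylbd.classifier import (
    FeatureModelConfig,
    NoApplicableModelError,
    Prediction,
    TripleLMConfig,
    TripleVocab,
    finetune_classifier,
    load_triple_lm,
    predict_importance,
    save_triple_lm,
    train_feature_model,
    train_triple_lm,
)
from noveltylbd.features import FeatureVector
from noveltylbd.labeling import ImportanceLabel, LabeledTriple
from noveltylbd.synthetic import gen_feature_training_data
from noveltylbd.triples import Triple
from conftest import make_predication


class TestFeatureModelArchitecture:
    def test_depth_four_gives_four_halving_hidden_layers(self):
        config = FeatureModelConfig(depth=4, first_layer_width=32)
        assert config.hidden_widths() == [32, 16, 8, 4]
        data = gen_feature_training_data(n_per_class=20, seed=0)
        models = train_feature_model(data, FeatureModelConfig(depth=4, epochs=2), seed=0)
        net = next(iter(models.values())).net
        assert net.sizes[1:] == [32, 16, 8, 4, 1]

    def test_width_floor_is_one(self):
        assert FeatureModelConfig(depth=4, first_layer_width=4).hidden_widths() == [4, 2, 1, 1]

    def test_dropout_zero_training_is_deterministic(self):
        data = gen_feature_training_data(n_per_class=30, seed=1)
        config = FeatureModelConfig(epochs=5, dropout=0.0)
        m1 = train_feature_model(data, config, seed=3)
        m2 = train_feature_model(data, config, seed=3)
        (k, model1), = m1.items()
        model2 = m2[k]
        for W1, W2 in zip(model1.net.W, model2.net.W):
            assert np.array_equal(W1, W2)


class TestFeatureModelRecovery:
    def test_separable_blobs_learned_and_cross_checked(self):
        """Training accuracy >= 0.95 on two separable Gaussian blobs, with an
        independent linear classifier confirming the data is separable."""
        data = gen_feature_training_data(n_per_class=500, seed=11)
        config = FeatureModelConfig(depth=4, epochs=60, first_layer_width=16)
        models = train_feature_model(data, config, seed=0)
        (model,) = models.values()
        preds = [model.predict(fv).label for fv, _ in data]
        labels = [y for _, y in data]
        acc = np.mean([p == y for p, y in zip(preds, labels)])
        assert acc >= 0.95
        # independent oracle: plain logistic regression on the same features
        from sklearn.linear_model import LogisticRegression

        X = np.array([[fv.textrank, fv.subject_depth, fv.object_depth] for fv, _ in data])
        lr = LogisticRegression().fit(X, labels)
        assert lr.score(X, labels) >= 0.95

    def test_single_class_pattern_skipped_with_warning(self, caplog):
        data = [(FeatureVector("body", textrank=0.5), 1)] * 5
        models = train_feature_model(data, FeatureModelConfig(epochs=1), seed=0)
        assert models == {}

    def test_probability_in_unit_interval(self):
        data = gen_feature_training_data(n_per_class=50, seed=2)
        models = train_feature_model(data, FeatureModelConfig(epochs=5), seed=0)
        (model,) = models.values()
        p = model.predict(data[0][0])
        assert 0.0 < p.probability < 1.0
        assert p.label == int(p.probability > 0.5)


class TestModelSelection:
    def _models(self):
        data = gen_feature_training_data(n_per_class=40, seed=5, missing_fraction=0.4)
        return train_feature_model(data, FeatureModelConfig(epochs=3), seed=0)

    def test_full_features_use_largest_pattern(self):
        models = self._models()
        assert set(models) == {"object_depth+subject_depth+textrank", "textrank"}
        fv = FeatureVector("body", textrank=0.5, subject_depth=2, object_depth=3)
        pred = predict_importance(models, make_predication(Triple("C0000001", "ISA", "C0000002")), fv)
        assert pred.model_used == "object_depth+subject_depth+textrank"

    def test_partial_features_fall_back(self):
        models = self._models()
        fv = FeatureVector("body", textrank=0.5)
        pred = predict_importance(models, make_predication(Triple("C0000001", "ISA", "C0000002")), fv)
        assert pred.model_used == "textrank"

    def test_no_applicable_model_errors(self):
        models = self._models()
        fv = FeatureVector("body")  # section only; no section-only model trained
        with pytest.raises(NoApplicableModelError):
            predict_importance(models, make_predication(Triple("C0000001", "ISA", "C0000002")), fv)

    def test_equal_size_tie_breaks_lexicographically(self):
        models = self._models()
        a = models["textrank"]
        b = models["object_depth+subject_depth+textrank"]
        # forge a same-size competitor with a lexicographically earlier id
        b.pattern = ("subject_depth",)
        b.mean, b.std = b.mean[:1], b.std[:1]
        b.net.sizes[0] = 3
        b.net.W[0] = b.net.W[0][:3, :]
        fv = FeatureVector("body", textrank=0.5, subject_depth=2)
        pred = predict_importance({"textrank": a, b.id: b},
                                  make_predication(Triple("C0000001", "ISA", "C0000002")), fv)
        assert pred.model_used == "subject_depth"


class TestTripleVocab:
    def test_triple_is_three_word_sentence(self):
        vocab = TripleVocab([Triple("C0012984", "ISA", "C0011847")], vocab_size=20)
        assert TripleVocab.tokenize(Triple("C0012984", "ISA", "C0011847")) == (
            "C0012984", "ISA", "C0011847",
        )
        ids = vocab.encode_triple(Triple("C0012984", "ISA", "C0011847"))
        assert len(ids) == 3 and len(set(ids.tolist())) == 3

    def test_frequency_then_lexicographic_order(self):
        triples = [
            Triple("B", "P", "A"), Triple("B", "P", "C"), Triple("A", "Q", "C"),
        ]
        vocab = TripleVocab(triples, vocab_size=20)
        content = vocab.tokens[5:]  # after the 5 special tokens
        # counts: A=2, B=2, C=2, P=2, Q=1 -> ties break lexicographically
        assert content == ["A", "B", "C", "P", "Q"]

    def test_overflow_maps_to_unknown(self):
        triples = [Triple("A", "P", "B"), Triple("C", "P", "D")]
        vocab = TripleVocab(triples, vocab_size=7)  # room for 2 content tokens
        assert len(vocab) == 7
        unk = vocab.encode("[UNK]")
        assert vocab.encode("D") == unk or vocab.encode("C") == unk


class TestTripleLM:
    MEMO_TRIPLES = [
        Triple("A", "P", "B"), Triple("B", "P", "C"), Triple("C", "Q", "A"),
    ]

    def _uniquely_determined(self, triples):
        """Exhaustive lookup: (context -> masked token) mappings that are unique."""
        out = []
        for t in triples:
            toks = TripleVocab.tokenize(t)
            for pos in range(3):
                context = tuple(tok for i, tok in enumerate(toks) if i != pos)
                matches = {
                    TripleVocab.tokenize(u)[pos]
                    for u in triples
                    if tuple(x for i, x in enumerate(TripleVocab.tokenize(u)) if i != pos) == context
                }
                if len(matches) == 1:
                    out.append((t, pos, toks[pos]))
        return out

    def test_memorizes_uniquely_determined_masked_elements(self):
        config = TripleLMConfig(vocab_size=16, hidden_layers=1, embedding_dim=8,
                                hidden_width=16, epochs=400, learning_rate=1e-2)
        lm = train_triple_lm(self.MEMO_TRIPLES, config, seed=0)
        cases = self._uniquely_determined(self.MEMO_TRIPLES)
        assert len(cases) == 9  # every masking is uniquely determined here
        for triple, pos, expected in cases:
            probs = lm.predict_masked(triple, pos)
            assert lm.vocab.tokens[int(np.argmax(probs))] == expected

    def test_same_seed_identical_embeddings(self):
        config = TripleLMConfig(vocab_size=16, embedding_dim=8, epochs=10)
        lm1 = train_triple_lm(self.MEMO_TRIPLES, config, seed=4)
        lm2 = train_triple_lm(self.MEMO_TRIPLES, config, seed=4)
        t = self.MEMO_TRIPLES[0]
        assert np.array_equal(lm1.triple_embedding(t), lm2.triple_embedding(t))

    def test_save_load_round_trip(self, tmp_path):
        config = TripleLMConfig(vocab_size=16, embedding_dim=8, epochs=5)
        lm = train_triple_lm(self.MEMO_TRIPLES, config, seed=1)
        save_triple_lm(lm, tmp_path / "model")
        loaded = load_triple_lm(tmp_path / "model")
        t = self.MEMO_TRIPLES[1]
        assert np.allclose(lm.predict_masked(t, 0), loaded.predict_masked(t, 0))
        assert np.array_equal(lm.triple_embedding(t), loaded.triple_embedding(t))


class TestFinetunedClassifier:
    def _labeled(self, n=40):
        out = []
        for i in range(n):
            important = i % 2 == 0
            if important:
                t = Triple(f"N{i}", "TREATS", f"M{i}")
                label, score = ImportanceLabel.IMPORTANT, 3.0
            else:
                t = Triple(f"G{i}", "ISA", f"H{i}")
                label, score = ImportanceLabel.NOT_IMPORTANT, 0.0
            out.append(LabeledTriple(make_predication(t, doc_id=f"D{i}"), score, label))
        return out

    def test_head_separates_disjoint_token_classes(self):
        labeled = self._labeled(60)
        triples = [lt.predication.triple for lt in labeled]
        lm = train_triple_lm(triples, TripleLMConfig(vocab_size=256, embedding_dim=8,
                                                     epochs=20), seed=2)
        clf = finetune_classifier(lm, labeled, seed=3)
        correct = 0
        for lt in labeled:
            pred = clf.predict(lt.predication.triple)
            assert 0.0 < pred.probability < 1.0
            assert pred.label == int(pred.probability > 0.5)
            correct += pred.label == (lt.label is ImportanceLabel.IMPORTANT)
        assert correct / len(labeled) >= 0.9

    def test_single_class_rejected(self):
        labeled = [lt for lt in self._labeled(10)
                   if lt.label is ImportanceLabel.IMPORTANT]
        triples = [lt.predication.triple for lt in labeled]
        lm = train_triple_lm(triples, TripleLMConfig(vocab_size=64, epochs=2), seed=0)
        with pytest.raises(ValueError):
            finetune_classifier(lm, labeled, seed=0)
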