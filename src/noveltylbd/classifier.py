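"""The two SPO-triple importance classifiers.

*Feature model* — a fully connected network over full-text features (section
one-hot, TextRank of the triple's sentence, CUI depths) with hidden layers of
halving widths, ReLU activations, a single sigmoid output node and binary
cross-entropy loss.  Because TextRank and the depths can be missing, a
separate model is trained per feature *availability pattern*, and at
prediction time the model using the highest number of available features is
selected.

*Triple language model* — each triple is treated as a three-word sentence
over a word-level vocabulary of CUIs and predicates (no subword splitting:
identifiers like ``C0012984`` have no meaningful subwords).  Training hides
exactly one of the three elements, chosen uniformly at random, and optimises
prediction of the masked element from the other two.  The learned token
embeddings give each triple a fixed-dimension embedding, over which a small
binary head is fine-tuned to predict importance.  Unlike the feature model,
this classifier needs no full text and applies to abstract-only articles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .features import FeatureVector
from .labeling import ImportanceLabel, LabeledTriple
from .nn import Adam, DenseNet
from .triples import Predication, Triple

__all__ = [
    "ModelKind",
    "FeatureModelConfig",
    "TripleLMConfig",
    "Prediction",
    "FeatureModel",
    "TripleLM",
    "TripleVocab",
    "TripleLMClassifier",
    "NoApplicableModelError",
    "train_feature_model",
    "train_triple_lm",
    "finetune_classifier",
    "predict_importance",
    "pattern_id",
]

logger = logging.getLogger(__name__)

SECTION_LABELS = ("abstract", "body")
DECISION_THRESHOLD = 0.5


class ModelKind(str, Enum):
    FEATURE = "feature"
    TRIPLE_LM = "triple_lm"


class NoApplicableModelError(LookupError):
    """No trained model's pattern is a subset of the available features."""


@dataclass(frozen=True)
class Prediction:
    label: int
    probability: float
    model_used: str


@dataclass(frozen=True)
class FeatureModelConfig:
    """Architecture/training settings for the feature network.

    ``depth`` hidden layers of halving widths starting at
    ``first_layer_width``, then a single sigmoid output node.
    """

    depth: int = 4
    epochs: int = 200
    dropout: float = 0.0
    first_layer_width: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 32

    def hidden_widths(self) -> list[int]:
        if self.depth < 1:
            raise ValueError("depth must be a positive integer")
        return [max(1, self.first_layer_width // (2 ** i)) for i in range(self.depth)]


def pattern_id(pattern: Sequence[str]) -> str:
    """Stable string id of an availability pattern ('' -> section only)."""
    return "+".join(sorted(pattern)) if pattern else "section_only"


class FeatureModel:
    """One trained feature network for a fixed availability pattern."""

    kind = ModelKind.FEATURE

    def __init__(self, pattern: tuple[str, ...], net: DenseNet,
                 mean: np.ndarray, std: np.ndarray):
        self.pattern = tuple(sorted(pattern))
        self.net = net
        self.mean = mean
        self.std = std

    @property
    def id(self) -> str:
        return pattern_id(self.pattern)

    def encode(self, fv: FeatureVector) -> np.ndarray:
        onehot = [1.0 if fv.section_name == s else 0.0 for s in SECTION_LABELS]
        numeric = []
        for name in self.pattern:
            value = getattr(fv, name)
            if value is None:
                raise ValueError(f"feature {name!r} unavailable for pattern {self.id}")
            numeric.append(float(value))
        x = np.array(onehot + numeric, dtype=np.float64)
        if self.pattern:
            x[len(onehot):] = (x[len(onehot):] - self.mean) / self.std
        return x

    def predict_proba(self, fv: FeatureVector) -> float:
        x = self.encode(fv)[None, :]
        return float(self.net.predict_proba(x)[0, 0])

    def predict(self, fv: FeatureVector) -> Prediction:
        p = self.predict_proba(fv)
        return Prediction(label=int(p > DECISION_THRESHOLD), probability=p,
                          model_used=self.id)


def _label_to_int(label: ImportanceLabel) -> int:
    return 1 if label is ImportanceLabel.IMPORTANT else 0


def train_feature_model(
    data: Iterable[tuple[FeatureVector, int]],
    config: FeatureModelConfig = FeatureModelConfig(),
    seed: int = 0,
) -> dict[str, FeatureModel]:
    """Train one model per availability pattern present in ``data``.

    ``data`` yields ``(feature_vector, label)`` with label 1 = important.
    Patterns whose data contain a single class are skipped with a warning.
    """
    groups: dict[tuple[str, ...], list[tuple[FeatureVector, int]]] = {}
    for fv, y in data:
        groups.setdefault(fv.availability_pattern, []).append((fv, y))
    models: dict[str, FeatureModel] = {}
    for k, (pattern, items) in enumerate(sorted(groups.items())):
        labels = {y for _, y in items}
        if len(labels) < 2:
            logger.warning(
                "pattern %s has a single class (%s); skipped", pattern_id(pattern), labels
            )
            continue
        numeric = np.array(
            [[float(getattr(fv, name)) for name in sorted(pattern)] for fv, _ in items]
        ) if pattern else np.zeros((len(items), 0))
        mean = numeric.mean(axis=0) if pattern else np.zeros(0)
        std = numeric.std(axis=0) if pattern else np.zeros(0)
        std = np.where(std == 0.0, 1.0, std)
        n_in = len(SECTION_LABELS) + len(pattern)
        sizes = [n_in] + config.hidden_widths() + [1]
        net = DenseNet(sizes, out_activation="sigmoid", dropout=config.dropout,
                       seed=seed + k)
        model = FeatureModel(tuple(sorted(pattern)), net, mean, std)
        X = np.stack([model.encode(fv) for fv, _ in items])
        y = np.array([y for _, y in items], dtype=np.float64)
        net.fit(X, y, epochs=config.epochs, lr=config.learning_rate,
                batch_size=config.batch_size)
        models[model.id] = model
    return models


def predict_importance(
    models: Mapping[str, FeatureModel],
    predication: Predication,
    features: FeatureVector,
) -> Prediction:
    """Apply the model with the largest pattern available for this triple.

    Among applicable models (pattern is a subset of the available features)
    the one using the most features wins; ties break to the
    lexicographically first pattern id.
    """
    available = set(features.availability_pattern)
    applicable = [m for m in models.values() if set(m.pattern) <= available]
    if not applicable:
        raise NoApplicableModelError(
            f"no model applies to availability pattern {pattern_id(tuple(available))}"
        )
    best = sorted(applicable, key=lambda m: (-len(m.pattern), m.id))[0]
    return best.predict(features)


# ---------------------------------------------------------------------------
# Masked-element triple language model
# ---------------------------------------------------------------------------

PAD, UNK, MASK, CLS, SEP = "[PAD]", "[UNK]", "[MASK]", "[CLS]", "[SEP]"
SPECIAL_TOKENS = (PAD, UNK, MASK, CLS, SEP)


@dataclass(frozen=True)
class TripleLMConfig:
    """Hyperparameters of the triple LM.

    ``vocab_size`` and ``hidden_layers`` are the tuned quantities; the mask
    policy is fixed: exactly one of the three positions is hidden, uniformly
    at random per training example.
    """

    vocab_size: int = 2000
    hidden_layers: int = 2
    embedding_dim: int = 16
    hidden_width: int = 64
    epochs: int = 30
    learning_rate: float = 5e-3
    batch_size: int = 64


class TripleVocab:
    """Word-level vocabulary over CUIs and predicates (no subword tokens).

    Entries are ordered: special tokens first, then observed tokens by
    descending frequency with lexicographic tie-break, truncated at
    ``vocab_size``; overflow tokens map to ``[UNK]``.
    """

    def __init__(self, triples: Iterable[Triple], vocab_size: int):
        counts: Counter[str] = Counter()
        for t in triples:
            counts.update(self.tokenize(t))
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        capacity = vocab_size - len(SPECIAL_TOKENS)
        if capacity < 0:
            raise ValueError("vocab_size smaller than the special-token set")
        if len(ordered) > capacity:
            logger.warning(
                "vocab_size %d holds %d of %d distinct tokens; overflow maps to %s",
                vocab_size, capacity, len(ordered), UNK,
            )
        self.tokens: list[str] = list(SPECIAL_TOKENS) + [t for t, _ in ordered[:capacity]]
        self._id = {tok: i for i, tok in enumerate(self.tokens)}

    @staticmethod
    def tokenize(triple: Triple) -> tuple[str, str, str]:
        """A triple is a three-word sentence: subject, predicate, object."""
        return (triple.subject_cui, triple.predicate, triple.object_cui)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._id

    def encode(self, token: str) -> int:
        return self._id.get(token, self._id[UNK])

    def encode_triple(self, triple: Triple) -> np.ndarray:
        return np.array([self.encode(t) for t in self.tokenize(triple)], dtype=np.int64)

    @property
    def mask_id(self) -> int:
        return self._id[MASK]


class TripleLM:
    """Masked-element language model over SPO triples.

    Token embeddings plus learned position embeddings for the three slots
    feed a feed-forward net with a softmax over the vocabulary.  The model
    yields a fixed ``3 * embedding_dim`` embedding per triple.
    """

    def __init__(self, vocab: TripleVocab, config: TripleLMConfig, seed: int = 0):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embedding_dim
        self.E = rng.normal(0.0, 0.1, size=(len(vocab), d))
        self.P = rng.normal(0.0, 0.1, size=(3, d))
        sizes = [3 * d] + [config.hidden_width] * config.hidden_layers + [len(vocab)]
        self.net = DenseNet(sizes, out_activation="softmax", seed=seed + 1)
        self._rng = rng

    # -- encoding ----------------------------------------------------------

    def _input_batch(self, ids: np.ndarray, masked_pos: Optional[np.ndarray]) -> np.ndarray:
        """Concatenate (token + position) embeddings; mask one slot if given."""
        n = ids.shape[0]
        d = self.config.embedding_dim
        use = ids.copy()
        if masked_pos is not None:
            use[np.arange(n), masked_pos] = self.vocab.mask_id
        X = np.empty((n, 3 * d))
        for pos in range(3):
            X[:, pos * d : (pos + 1) * d] = self.E[use[:, pos]] + self.P[pos]
        return X, use

    def triple_embedding(self, triple: Triple) -> np.ndarray:
        ids = self.vocab.encode_triple(triple)[None, :]
        X, _ = self._input_batch(ids, None)
        return X[0]

    def embed_triples(self, triples: Sequence[Triple]) -> np.ndarray:
        ids = np.stack([self.vocab.encode_triple(t) for t in triples])
        X, _ = self._input_batch(ids, None)
        return X

    # -- masked-element prediction ------------------------------------------

    def predict_masked(self, triple: Triple, position: int) -> np.ndarray:
        """Probability over the vocabulary for the token at ``position``."""
        if position not in (0, 1, 2):
            raise ValueError("position must be 0 (subject), 1 (predicate) or 2 (object)")
        ids = self.vocab.encode_triple(triple)[None, :]
        X, _ = self._input_batch(ids, np.array([position]))
        return self.net.predict_proba(X)[0]

    # -- training -----------------------------------------------------------

    def fit(self, triples: Sequence[Triple]) -> list[float]:
        cfg = self.config
        ids_all = np.stack([self.vocab.encode_triple(t) for t in triples])
        n = ids_all.shape[0]
        d = cfg.embedding_dim
        opt = Adam([self.E, self.P] + self.net.params(), lr=cfg.learning_rate)
        history: list[float] = []
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            masked_pos = self._rng.integers(0, 3, size=n)  # one element per example
            losses = []
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                ids = ids_all[sel]
                pos = masked_pos[sel]
                X, used = self._input_batch(ids, pos)
                targets = ids_all[sel][np.arange(len(sel)), pos]
                out, cache = self.net.forward(X, train=True)
                loss, delta = self.net.loss_and_delta(out, targets)
                gW, gb, dX = self.net.backward(cache, delta)
                gE = np.zeros_like(self.E)
                gP = np.zeros_like(self.P)
                for p in range(3):
                    sl = dX[:, p * d : (p + 1) * d]
                    np.add.at(gE, used[:, p], sl)
                    gP[p] = sl.sum(axis=0)
                opt.step([self.E, self.P] + self.net.params(), [gE, gP] + gW + gb)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history


def train_triple_lm(
    triples: Iterable[Triple],
    config: TripleLMConfig = TripleLMConfig(),
    seed: int = 0,
) -> TripleLM:
    """Build the word-level vocabulary and train the masked triple LM."""
    triples = list(triples)
    if not triples:
        raise ValueError("at least one triple is required")
    vocab = TripleVocab(triples, config.vocab_size)
    lm = TripleLM(vocab, config, seed=seed)
    lm.fit(triples)
    return lm


class TripleLMClassifier:
    """Binary importance head over triple-LM embeddings."""

    kind = ModelKind.TRIPLE_LM

    def __init__(self, lm: TripleLM, head: DenseNet):
        self.lm = lm
        self.head = head

    def predict_proba(self, triple: Triple) -> float:
        x = self.lm.triple_embedding(triple)[None, :]
        return float(self.head.predict_proba(x)[0, 0])

    def predict(self, triple: Triple) -> Prediction:
        p = self.predict_proba(triple)
        return Prediction(label=int(p > DECISION_THRESHOLD), probability=p,
                          model_used=ModelKind.TRIPLE_LM.value)

    def predict_many(self, triples: Sequence[Triple]) -> list[Prediction]:
        X = self.lm.embed_triples(triples)
        probs = self.head.predict_proba(X)[:, 0]
        return [
            Prediction(label=int(p > DECISION_THRESHOLD), probability=float(p),
                       model_used=ModelKind.TRIPLE_LM.value)
            for p in probs
        ]


def save_triple_lm(lm: TripleLM, directory) -> None:
    """Persist a triple LM to a versioned directory (config JSON + weights)."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "format_version": 1,
        "kind": ModelKind.TRIPLE_LM.value,
        "config": {
            "vocab_size": lm.config.vocab_size,
            "hidden_layers": lm.config.hidden_layers,
            "embedding_dim": lm.config.embedding_dim,
            "hidden_width": lm.config.hidden_width,
            "epochs": lm.config.epochs,
            "learning_rate": lm.config.learning_rate,
            "batch_size": lm.config.batch_size,
        },
        "vocab": lm.vocab.tokens,
    }
    with (directory / "config.json").open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
    arrays = {"E": lm.E, "P": lm.P}
    for i, (W, b) in enumerate(zip(lm.net.W, lm.net.b)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)


def load_triple_lm(directory) -> TripleLM:
    """Load a triple LM persisted by :func:`save_triple_lm`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    with (directory / "config.json").open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != 1:
        raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
    config = TripleLMConfig(**doc["config"])
    vocab = TripleVocab.__new__(TripleVocab)
    vocab.tokens = list(doc["vocab"])
    vocab._id = {tok: i for i, tok in enumerate(vocab.tokens)}
    lm = TripleLM(vocab, config)
    with np.load(directory / "weights.npz") as data:
        lm.E = data["E"]
        lm.P = data["P"]
        for i in range(len(lm.net.W)):
            lm.net.W[i] = data[f"W{i}"]
            lm.net.b[i] = data[f"b{i}"]
    return lm


def finetune_classifier(
    lm: TripleLM,
    labeled: Iterable[LabeledTriple],
    seed: int = 0,
    epochs: int = 150,
    learning_rate: float = 1e-3,
) -> TripleLMClassifier:
    """Fine-tune a binary head on labelled triples (gap instances excluded)."""
    instances = [lt for lt in labeled if lt.label is not ImportanceLabel.DISCARDED_GAP]
    y = np.array([_label_to_int(lt.label) for lt in instances], dtype=np.float64)
    if len(set(y.tolist())) < 2:
        raise ValueError("fine-tuning requires both classes")
    X = lm.embed_triples([lt.predication.triple for lt in instances])
    d_in = X.shape[1]
    head = DenseNet([d_in, 16, 1], out_activation="sigmoid", seed=seed)
    head.fit(X, y, epochs=epochs, lr=learning_rate, batch_size=32)
    return TripleLMClassifier(lm, head)
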