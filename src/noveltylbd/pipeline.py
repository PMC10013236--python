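"""End-to-end pipeline: label -> train -> predict -> discover -> evaluate.

A run is described by a :class:`RunConfig` (a versioned JSON document); every
random operation receives a seed derived from the config, intermediate
artifacts (labelled set, CHKP exports, reports) are persisted to the run
directory alongside the exact config that produced them, and each stage
appends one JSON log line with its counts (triples in, triples important,
CHKPs out).  A run therefore reproduces bit-exactly from its config.

The discovery stage supports three triple sources, mirroring the comparison
the evaluation is built for: ``all`` (every distinct pre-cutoff triple),
``abstract`` (pre-cutoff abstract triples only — the unfiltered baseline)
and ``important`` (triples the importance classifier keeps).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import labeling
from .classifier import TripleLMConfig, finetune_classifier, train_triple_lm
from .discovery import write_chkps
from .embeddings import EmbeddingKind, load_embeddings, save_embeddings
from .evaluation import GoldVariant, evaluate
from .labeling import ImportanceLabel, SimilarityConfig, build_training_set
from .synthetic import SyntheticSpec, gen_corpus, gen_embeddings
from .triples import (
    Corpus,
    Section,
    distinct_triples,
    filter_corpus,
    read_predications,
    write_predications,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the stage name is included in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All parameters of one pipeline run (JSON round-trippable)."""

    outdir: str
    seed: int = 0
    cutoff: _dt.date = _dt.date(2021, 1, 1)
    # classifier training slice: post-cutoff but before this date, so the
    # training data cannot overlap the pre-cutoff discovery input
    train_window_end: _dt.date = _dt.date(2021, 3, 29)
    hi: float = 2.5
    lo: float = 1.5
    classifier: str = "triple_lm"  # "triple_lm" or "labels"
    triples_sources: tuple[str, ...] = ("all", "abstract", "important")
    gold_variants: tuple[str, ...] = (
        GoldVariant.ALL.value,
        GoldVariant.ABSTRACT.value,
        GoldVariant.IMPORTANT.value,
    )
    # inputs: either a synthetic spec or paths to prepared files
    synthetic: Optional[dict] = None
    predications_path: Optional[str] = None
    concept_embeddings_path: Optional[str] = None
    predicate_embeddings_path: Optional[str] = None
    lm: dict = field(default_factory=dict)  # TripleLMConfig overrides

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["schema_version"] = SCHEMA_VERSION
        doc["cutoff"] = self.cutoff.isoformat()
        doc["train_window_end"] = self.train_window_end.isoformat()
        doc["triples_sources"] = list(self.triples_sources)
        doc["gold_variants"] = list(self.gold_variants)
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
        version = doc.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version!r}")
        doc["cutoff"] = _dt.date.fromisoformat(doc["cutoff"])
        doc["train_window_end"] = _dt.date.fromisoformat(doc["train_window_end"])
        doc["triples_sources"] = tuple(doc["triples_sources"])
        doc["gold_variants"] = tuple(doc["gold_variants"])
        return cls(**doc)


def _synthetic_spec(doc: dict) -> SyntheticSpec:
    doc = dict(doc)
    for key in ("cutoff", "pre_window_start", "post_window_end"):
        if key in doc and isinstance(doc[key], str):
            doc[key] = _dt.date.fromisoformat(doc[key])
    if "planted_hidden" in doc and doc["planted_hidden"] is not None:
        doc["planted_hidden"] = tuple(tuple(c) for c in doc["planted_hidden"])
    return SyntheticSpec(**doc)


def run_pipeline(config: RunConfig):
    """Execute the full pipeline; returns ``{triples_source: EvalReport}``.

    Artifacts written to ``config.outdir``: the config itself, the corpus and
    embedding files (for synthetic runs), the labelled training set, one CHKP
    export / report / undiscovered-pairs export per triple source, and a
    JSON-lines stage log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    log_path = outdir / "run_log.jsonl"
    log_fh = log_path.open("w", encoding="utf-8")

    def log(stage: str, **counts) -> None:
        log_fh.write(json.dumps({"stage": stage, **counts}, sort_keys=True) + "\n")
        log_fh.flush()

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # persist partial artifacts, name the stage
            log(stage, error=str(exc))
            log_fh.close()
            raise PipelineError(stage, exc) from exc

    # ---- inputs -----------------------------------------------------------
    def load_inputs():
        if config.synthetic is not None:
            spec = _synthetic_spec({**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
            corpus = gen_corpus(spec)
            concepts, predicates = gen_embeddings(spec)
            write_predications(corpus, outdir / "corpus.tsv")
            save_embeddings(concepts, outdir / "concepts.vec")
            save_embeddings(predicates, outdir / "predicates.vec")
        else:
            if not (config.predications_path and config.concept_embeddings_path
                    and config.predicate_embeddings_path):
                raise ValueError("config needs either a synthetic spec or input paths")
            corpus = read_predications(config.predications_path)
            concepts = load_embeddings(config.concept_embeddings_path, EmbeddingKind.CONCEPT)
            predicates = load_embeddings(config.predicate_embeddings_path, EmbeddingKind.PREDICATE)
        return corpus, concepts, predicates

    corpus, concepts, predicates = run_stage("inputs", load_inputs)
    log("inputs", predications=len(corpus), concepts=len(concepts),
        predicates=len(predicates))

    # ---- timeslice --------------------------------------------------------
    pre = filter_corpus(corpus, before=config.cutoff)
    post = filter_corpus(corpus, on_or_after=config.cutoff)
    log("timeslice", pre=len(pre), post=len(post),
        cutoff=config.cutoff.isoformat())

    # ---- label ------------------------------------------------------------
    sim_config = SimilarityConfig(hi=config.hi, lo=config.lo)

    def label_stage():
        train_slice = filter_corpus(post, before=config.train_window_end)
        result = build_training_set(train_slice, concepts, predicates, sim_config)
        labeling.write_labeled(result.labeled, outdir / "labeled.tsv")
        return result

    label_result = run_stage("label", label_stage)
    log("label",
        labeled=len(label_result.labeled),
        important=len(label_result.by_label(ImportanceLabel.IMPORTANT)),
        not_important=len(label_result.by_label(ImportanceLabel.NOT_IMPORTANT)),
        discarded_gap=len(label_result.by_label(ImportanceLabel.DISCARDED_GAP)),
        docs_without_abstract=label_result.docs_without_abstract,
        skipped_missing_embedding=label_result.skipped_missing_embedding)

    # ---- importance -------------------------------------------------------
    all_triples = distinct_triples(corpus)
    pre_triples = distinct_triples(pre)
    post_triples = distinct_triples(post)

    def importance_stage():
        need_important = (
            "important" in config.triples_sources
            or GoldVariant.IMPORTANT.value in config.gold_variants
        )
        if not need_important:
            return None, None
        if config.classifier == "labels":
            # oracle mode: importance by the similarity labels themselves
            post_result = build_training_set(post, concepts, predicates, sim_config)
            important_post = {
                lt.predication.triple for lt in post_result.labeled
                if lt.label is ImportanceLabel.IMPORTANT
            }
            pre_result = build_training_set(pre, concepts, predicates, sim_config)
            important_pre = {
                lt.predication.triple for lt in pre_result.labeled
                if lt.label is ImportanceLabel.IMPORTANT
            }
            return important_pre, important_post
        if config.classifier != "triple_lm":
            raise ValueError(f"unknown classifier {config.classifier!r}")
        balanced = labeling.balance_by_undersampling(
            label_result.training_instances(), seed=config.seed
        )
        lm = train_triple_lm(sorted(all_triples),
                             TripleLMConfig(**config.lm), seed=config.seed)
        clf = finetune_classifier(lm, balanced, seed=config.seed + 1)
        ordered_pre = sorted(pre_triples)
        ordered_post = sorted(post_triples)
        important_pre = {
            t for t, p in zip(ordered_pre, clf.predict_many(ordered_pre)) if p.label == 1
        }
        important_post = {
            t for t, p in zip(ordered_post, clf.predict_many(ordered_post)) if p.label == 1
        }
        return important_pre, important_post

    important_pre, important_post = run_stage("importance", importance_stage)
    log("importance",
        pre_triples=len(pre_triples),
        pre_important=len(important_pre) if important_pre is not None else None,
        post_triples=len(post_triples),
        post_important=len(important_post) if important_post is not None else None,
        classifier=config.classifier)

    # ---- discover + evaluate ---------------------------------------------
    sources = {
        "all": pre_triples,
        "abstract": distinct_triples(filter_corpus(pre, section=Section.ABSTRACT)),
        "important": important_pre,
    }
    reports = {}
    for source in config.triples_sources:
        def eval_stage(source=source):
            triples = sources[source]
            if triples is None:
                raise ValueError(f"triple source {source!r} requires importance predictions")
            variants = [GoldVariant(v) for v in config.gold_variants]
            report, chkps = evaluate(
                sorted(triples), post, variants,
                important_triples=important_post, triples_source=source,
            )
            write_chkps(chkps, outdir / f"chkps_{source}.tsv")
            report.to_json(outdir / f"report_{source}.json")
            report.to_tsv(outdir / f"report_{source}.tsv")
            with (outdir / f"undiscovered_{source}.tsv").open("w", encoding="utf-8") as fh:
                fh.write("source_cui\ttarget_cui\n")
                for a, b in report.undiscovered:
                    fh.write(f"{a}\t{b}\n")
            return report
        report = run_stage(f"evaluate[{source}]", eval_stage)
        reports[source] = report
        log(f"evaluate[{source}]", triples_in=len(sources[source] or ()),
            total_chkps=report.total_chkps,
            **{f"precision_{k}": round(v, 6) for k, v in report.precisions.items()})

    log_fh.close()
    return reports
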