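"""Timeslicing evaluation of candidate hidden knowledge pairs.

CHKPs are generated from relations in publications dated strictly before a
cutoff date D; relations appearing on or after D form the gold standard.
Three gold-standard variants are supported, decreasingly contaminated by
background knowledge: all post-cutoff triples, post-cutoff abstract triples
only, and post-cutoff triples labelled important.  Precision — the fraction
of CHKPs found in the gold standard — is the reported measure; recall is
deliberately not reported by default, since producing every inferable pair
trivially maximises it.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .discovery import CHKPSet, build_graph, extract_chkps
from .triples import Corpus, Section, Triple, distinct_triples, filter_corpus

__all__ = [
    "GoldVariant",
    "GoldStandard",
    "EvalReport",
    "UndefinedPrecisionError",
    "timeslice",
    "build_gold_standard",
    "precision",
    "evaluate",
]


class GoldVariant(str, Enum):
    ALL = "all_post_triples"
    ABSTRACT = "post_abstract_triples"
    IMPORTANT = "post_important_triples"


class UndefinedPrecisionError(ZeroDivisionError):
    """Precision of an empty CHKP set is undefined, not zero."""


@dataclass(frozen=True)
class GoldStandard:
    variant: GoldVariant
    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EvalReport:
    """Per-variant precision of one CHKP set, plus gold sizes and exports."""

    triples_source: str
    total_chkps: int
    precisions: dict[str, float] = field(default_factory=dict)
    gold_sizes: dict[str, int] = field(default_factory=dict)
    # CHKPs found in no gold standard: the "as yet undiscovered" pairs
    undiscovered: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "triples_source": self.triples_source,
            "total_chkps": self.total_chkps,
            "gold_sizes": dict(sorted(self.gold_sizes.items())),
            # precision is stated both ways because "percentage precision"
            # tables are ambiguous between proportions and percentages
            "precision": {
                k: round(v, 6) for k, v in sorted(self.precisions.items())
            },
            "precision_percent": {
                k: round(100.0 * v, 4) for k, v in sorted(self.precisions.items())
            },
            "n_undiscovered": len(self.undiscovered),
        }

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=False)
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        variants = sorted(self.precisions)
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("triples_source\ttotal_chkps\t" + "\t".join(variants) + "\n")
            row = [self.triples_source, str(self.total_chkps)] + [
                f"{self.precisions[v]:.3g}" for v in variants
            ]
            fh.write("\t".join(row) + "\n")


def timeslice(corpus: Corpus, cutoff: _dt.date) -> tuple[Corpus, Corpus]:
    """Partition a corpus at the cutoff: (date < D, date >= D)."""
    pre = filter_corpus(corpus, before=cutoff)
    post = filter_corpus(corpus, on_or_after=cutoff)
    return pre, post


def build_gold_standard(
    post: Corpus,
    variant: GoldVariant,
    important_triples: Optional[Iterable[Triple]] = None,
) -> GoldStandard:
    """De-duplicated (subject, object) pairs of the selected post triples."""
    variant = GoldVariant(variant)
    if variant is GoldVariant.ALL:
        triples = distinct_triples(post)
    elif variant is GoldVariant.ABSTRACT:
        triples = distinct_triples(filter_corpus(post, section=Section.ABSTRACT))
    else:
        if important_triples is None:
            raise ValueError(
                "the important-triple gold standard needs importance labels/predictions"
            )
        important = set(important_triples)
        triples = {t for t in distinct_triples(post) if t in important}
    pairs = frozenset((t.subject_cui, t.object_cui) for t in triples)
    return GoldStandard(variant=variant, pairs=pairs)


def precision(chkps: CHKPSet, gold: GoldStandard, unordered: bool = False) -> float:
    """|CHKP pairs found in gold| / |CHKP pairs|.

    Pairs are matched as ordered (subject, object) pairs, like the directed
    CHKPs; ``unordered`` also accepts the reversed gold pair.
    """
    if len(chkps) == 0:
        raise UndefinedPrecisionError("precision of an empty CHKP set is undefined")
    if unordered:
        gold_pairs = set(gold.pairs) | {(b, a) for a, b in gold.pairs}
    else:
        gold_pairs = gold.pairs
    hits = sum(1 for p in chkps.pairs if p in gold_pairs)
    return hits / len(chkps)


def evaluate(
    pre_triples: Iterable[Triple],
    post: Corpus,
    variants: Sequence[GoldVariant] = (),
    important_triples: Optional[Iterable[Triple]] = None,
    triples_source: str = "all",
) -> tuple[EvalReport, CHKPSet]:
    """Run discovery on the pre-cutoff triples and score against each gold.

    Returns the report and the CHKP set itself.  CHKPs appearing in no gold
    standard are collected in ``report.undiscovered`` (candidate pairs still
    unconfirmed by later literature).
    """
    graph = build_graph(pre_triples)
    chkps = extract_chkps(graph)
    important = list(important_triples) if important_triples is not None else None
    report = EvalReport(triples_source=triples_source, total_chkps=len(chkps))
    golds = []
    for variant in variants:
        gold = build_gold_standard(post, variant, important_triples=important)
        golds.append(gold)
        report.gold_sizes[GoldVariant(variant).value] = len(gold)
        report.precisions[GoldVariant(variant).value] = (
            precision(chkps, gold) if len(chkps) else 0.0
        )
    all_gold_pairs: set[tuple[str, str]] = set()
    for g in golds:
        all_gold_pairs |= g.pairs
    report.undiscovered = sorted(p for p in chkps.pairs if p not in all_gold_pairs)
    return report, chkps
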