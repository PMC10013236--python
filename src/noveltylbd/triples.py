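"""Reading, writing and filtering corpora of SPO predications.

A *predication* is one dated occurrence of a subject-predicate-object (SPO)
triple in a document section (abstract or body), in the style of SemMedDB /
SemRep exports.  Since exports of such databases vary in layout, this module
fixes one documented tab-separated dialect so that round-trips are bit-exact:

    #doc_id<TAB>date<TAB>section<TAB>sentence_index<TAB>sentence_text<TAB>subject_cui<TAB>predicate<TAB>object_cui

One header line starting with ``#``; dates are ISO-8601 (YYYY-MM-DD); the
missing-value token is ``-``.  UMLS concept identifiers (CUIs) have the form
``C`` followed by seven digits; validation against that pattern is optional so
synthetic identifiers can be used freely.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Triple",
    "Section",
    "Predication",
    "Corpus",
    "CorpusFormatError",
    "read_predications",
    "write_predications",
    "filter_corpus",
    "distinct_triples",
]

CUI_PATTERN = re.compile(r"^C[0-9]{7}$")
_MISSING = "-"
_HEADER = "#doc_id\tdate\tsection\tsentence_index\tsentence_text\tsubject_cui\tpredicate\tobject_cui"
_PREDICATE_PATTERN = re.compile(r"^[A-Z0-9_]+$")


class CorpusFormatError(ValueError):
    """A predication file line violated the documented dialect."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class Section(str, Enum):
    """Document section a predication was extracted from."""

    ABSTRACT = "abstract"
    BODY = "body"


@dataclass(frozen=True, order=True)
class Triple:
    """A subject-predicate-object relation between two concepts (CUIs)."""

    subject_cui: str
    predicate: str
    object_cui: str

    def validate(self, check_cuis: bool = False) -> None:
        if not self.predicate or not _PREDICATE_PATTERN.match(self.predicate):
            raise ValueError(
                f"predicate must be a non-empty uppercase token, got {self.predicate!r}"
            )
        if check_cuis:
            for cui in (self.subject_cui, self.object_cui):
                if not CUI_PATTERN.match(cui):
                    raise ValueError(f"invalid CUI {cui!r} (expected C followed by 7 digits)")

    def __str__(self) -> str:  # e.g. "C0011847 PROCESS_OF C0030705"
        return f"{self.subject_cui} {self.predicate} {self.object_cui}"


@dataclass(frozen=True)
class Predication:
    """One dated, sectioned occurrence of a triple in a document."""

    doc_id: str
    date: _dt.date
    section: Section
    triple: Triple
    sentence_index: Optional[int] = None
    sentence_text: Optional[str] = None


@dataclass
class Corpus:
    """An ordered collection of predications."""

    predications: list[Predication] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.predications)

    def __iter__(self) -> Iterator[Predication]:
        return iter(self.predications)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.predications == other.predications

    def doc_ids(self) -> list[str]:
        """Document identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.predications:
            seen.setdefault(p.doc_id, None)
        return list(seen)


def _parse_line(line: str, lineno: int, validate_cuis: bool) -> Predication:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise CorpusFormatError(
            f"expected 8 tab-separated fields, got {len(fields)}", lineno
        )
    doc_id, date_s, section_s, sent_idx_s, sent_text, subj, pred, obj = fields[:8]
    try:
        date = _dt.date.fromisoformat(date_s)
    except ValueError as exc:
        raise CorpusFormatError(f"unparseable date {date_s!r}: {exc}", lineno) from exc
    try:
        section = Section(section_s)
    except ValueError as exc:
        valid = "/".join(s.value for s in Section)
        raise CorpusFormatError(
            f"bad section value {section_s!r} (expected {valid})", lineno
        ) from exc
    sentence_index: Optional[int] = None
    if sent_idx_s != _MISSING:
        try:
            sentence_index = int(sent_idx_s)
        except ValueError as exc:
            raise CorpusFormatError(
                f"bad sentence_index {sent_idx_s!r}", lineno
            ) from exc
        if sentence_index < 0:
            raise CorpusFormatError(
                f"sentence_index must be non-negative, got {sentence_index}", lineno
            )
    sentence_text = None if sent_text == _MISSING else sent_text
    triple = Triple(subj, pred, obj)
    try:
        triple.validate(check_cuis=validate_cuis)
    except ValueError as exc:
        raise CorpusFormatError(str(exc), lineno) from exc
    return Predication(
        doc_id=doc_id,
        date=date,
        section=section,
        triple=triple,
        sentence_index=sentence_index,
        sentence_text=sentence_text,
    )


def read_predications(path: str | Path, validate_cuis: bool = False) -> Corpus:
    """Read a predication TSV file into a :class:`Corpus`.

    Lines starting with ``#`` are headers/comments.  Malformed lines raise
    :class:`CorpusFormatError` carrying the 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    predications: list[Predication] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            predications.append(_parse_line(line, lineno, validate_cuis))
    return Corpus(predications)


def write_predications(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the documented TSV dialect (re-readable losslessly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for p in corpus:
            sent_idx = _MISSING if p.sentence_index is None else str(p.sentence_index)
            sent_text = _MISSING if p.sentence_text is None else p.sentence_text
            fh.write(
                "\t".join(
                    (
                        p.doc_id,
                        p.date.isoformat(),
                        p.section.value,
                        sent_idx,
                        sent_text,
                        p.triple.subject_cui,
                        p.triple.predicate,
                        p.triple.object_cui,
                    )
                )
                + "\n"
            )


def filter_corpus(
    corpus: Corpus,
    section: Optional[Section] = None,
    before: Optional[_dt.date] = None,
    on_or_after: Optional[_dt.date] = None,
) -> Corpus:
    """Select predications matching all given predicates, preserving order.

    The timeslice convention is strict: ``date < before`` is the "pre" side
    and ``date >= on_or_after`` is the "post" side, so ``before=D`` and
    ``on_or_after=D`` partition any corpus with no overlap.
    """
    if before is not None and on_or_after is not None and on_or_after >= before:
        # both bounds form a window [on_or_after, before)
        pass
    out = []
    for p in corpus:
        if section is not None and p.section is not section:
            continue
        if before is not None and not p.date < before:
            continue
        if on_or_after is not None and not p.date >= on_or_after:
            continue
        out.append(p)
    return Corpus(out)


def distinct_triples(corpus: Corpus | Iterable[Predication]) -> set[Triple]:
    """The set of distinct (subject, predicate, object) triples in a corpus."""
    return {p.triple for p in corpus}
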