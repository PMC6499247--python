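"""Annotated-corpus I/O: PubTator and JSON-lines formats, sentence segmentation.

Documents are titles+abstracts with character-offset entity annotations.
Offsets are 0-based half-open into the title+abstract concatenation, the two
parts joined by a single space (PubTator convention).
"""

from __future__ import annotations

import bisect
import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("Gene", "Chemical", "Disease", "Species", "Mutation", "Hallmark")


class CorpusFormatError(ValueError):
    """Raised on malformed input records; message carries line/doc context."""


@dataclass(frozen=True)
class SentenceSpan:
    """Half-open character span of one sentence within a document's text."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty sentence span [{self.start},{self.end})")


@dataclass
class Document:
    doc_id: str
    text: str
    year: Optional[int] = None
    sentences: list[SentenceSpan] = field(default_factory=list)


@dataclass(frozen=True)
class Mention:
    """One textual occurrence of an entity, optionally grounded to an identifier.

    ``entity_id`` of ``None`` means the mention is ungrounded; such mentions are
    kept in mention-level data but never contribute to the entity graph.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    entity_type: str
    entity_id: Optional[str] = None
    sentence_index: Optional[int] = None


# ---------------------------------------------------------------------------
# PubTator format
# ---------------------------------------------------------------------------

_TITLE_RE = re.compile(r"^([^|]+)\|t\|(.*)$")
_ABSTRACT_RE = re.compile(r"^([^|]+)\|a\|(.*)$")


def read_year_sidecar(stream: IO[str]) -> dict[str, int]:
    """Read a two-column TSV mapping doc_id to publication year."""
    years: dict[str, int] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise CorpusFormatError(f"year sidecar line {lineno}: expected 2 columns")
        try:
            years[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise CorpusFormatError(f"year sidecar line {lineno}: bad year {parts[1]!r}") from exc
    return years


def read_pubtator(
    stream: IO[str],
    years: Optional[dict[str, int]] = None,
    default_year: Optional[int] = None,
) -> tuple[list[Document], list[Mention]]:
    """Parse a PubTator-format stream into documents and mentions.

    Records are blank-line separated: a ``PMID|t|title`` line, a ``PMID|a|abstract``
    line, then zero or more TAB-separated annotation lines
    ``PMID <TAB> start <TAB> end <TAB> surface <TAB> type <TAB> id``.
    Document text is title + " " + abstract.  Annotations whose offsets do not
    match the surface text are skipped with a warning.  An identifier field of
    ``"-"`` or empty yields an ungrounded mention.  Records with duplicate
    title/abstract lines are rejected (skipped with a warning).

    ``years`` maps doc_id to publication year; documents without a year fall
    back to ``default_year`` (year stays ``None`` if that is unset too).
    """
    years = years or {}
    documents: list[Document] = []
    mentions: list[Mention] = []

    record: list[tuple[int, str]] = []

    def flush(record: list[tuple[int, str]]) -> None:
        if not record:
            return
        title: Optional[str] = None
        abstract: Optional[str] = None
        doc_id: Optional[str] = None
        ann_lines: list[tuple[int, str]] = []
        for lineno, line in record:
            m = _TITLE_RE.match(line)
            if m:
                if title is not None:
                    logger.warning("line %d: duplicate title line for %s; record rejected",
                                   lineno, doc_id)
                    return
                doc_id, title = m.group(1), m.group(2)
                continue
            m = _ABSTRACT_RE.match(line)
            if m:
                if abstract is not None:
                    logger.warning("line %d: duplicate abstract line for %s; record rejected",
                                   lineno, doc_id)
                    return
                abstract = m.group(2)
                continue
            ann_lines.append((lineno, line))
        if doc_id is None or title is None:
            lineno = record[0][0]
            raise CorpusFormatError(f"line {lineno}: record without a title line")
        text = title if abstract is None or abstract == "" else f"{title} {abstract}"
        doc = Document(doc_id=doc_id, text=text,
                       year=years.get(doc_id, default_year))
        documents.append(doc)
        for lineno, line in ann_lines:
            parts = line.split("\t")
            if len(parts) < 5:
                raise CorpusFormatError(
                    f"line {lineno}: annotation needs >=5 tab-separated fields")
            ann_id, s, e, surface, etype = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ann_id != doc_id:
                raise CorpusFormatError(
                    f"line {lineno}: annotation PMID {ann_id!r} != record PMID {doc_id!r}")
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: non-integer offsets") from exc
            entity_id = parts[5] if len(parts) > 5 else ""
            if entity_id in ("", "-"):
                entity_id = None
            if text[start:end] != surface:
                logger.warning(
                    "line %d: offset mismatch in %s: text[%d:%d]=%r != %r; skipped",
                    lineno, doc_id, start, end, text[start:end], surface)
                continue
            mentions.append(Mention(doc_id=doc_id, start=start, end=end,
                                    surface=surface, entity_type=etype,
                                    entity_id=entity_id))

    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if line.strip() == "":
            flush(record)
            record = []
        else:
            record.append((lineno, line))
    flush(record)
    return documents, mentions


def write_pubtator(documents: Iterable[Document], mentions: Iterable[Mention],
                   stream: IO[str]) -> None:
    """Write documents and mentions back out in PubTator format.

    The title/abstract split is recovered from the first sentence boundary if
    sentences are populated, else the whole text is written as the title.
    """
    by_doc: dict[str, list[Mention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    for doc in documents:
        if doc.sentences:
            split = doc.sentences[0].end
            title, rest = doc.text[:split], doc.text[split:].lstrip(" ")
        else:
            title, rest = doc.text, ""
        stream.write(f"{doc.doc_id}|t|{title}\n")
        stream.write(f"{doc.doc_id}|a|{rest}\n")
        for m in sorted(by_doc.get(doc.doc_id, []), key=lambda m: (m.start, m.end)):
            eid = m.entity_id if m.entity_id is not None else "-"
            stream.write(f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.entity_type}\t{eid}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

#: Tokens (including the trailing period) that never end a sentence.
ABBREVIATIONS = frozenset({
    "E.", "B.", "S.", "H.", "M.", "C.", "D.", "L.", "P.", "R.", "T.",
    "e.g.", "i.e.", "cf.", "et al.", "al.", "vs.", "ca.", "approx.",
    "Fig.", "Figs.", "Dr.", "Prof.", "St.", "no.", "No.", "resp.",
})

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")


def segment_sentences(document: Document,
                      abbreviations: frozenset[str] = ABBREVIATIONS) -> Document:
    """Populate ``document.sentences`` by deterministic rule-based splitting.

    A boundary is sentence-final punctuation followed by whitespace and an
    uppercase letter or digit, unless the token ending in the punctuation is on
    the abbreviation guard list.  Text with no boundary becomes one sentence.
    """
    text = document.text
    if not text.strip():
        raise ValueError(f"document {document.doc_id}: empty text")
    boundaries: list[int] = []  # index just past the punctuation
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        token_start = text.rfind(" ", 0, m.start()) + 1
        token = text[token_start:end]
        if token in abbreviations:
            continue
        boundaries.append(end)

    spans: list[SentenceSpan] = []
    pos = 0
    for b in boundaries:
        start = _skip_ws(text, pos)
        spans.append(SentenceSpan(index=len(spans), start=start, end=b))
        pos = b
    start = _skip_ws(text, pos)
    if start < len(text):
        end = len(text)
        while end > start and text[end - 1].isspace():
            end -= 1
        spans.append(SentenceSpan(index=len(spans), start=start, end=end))
    document.sentences = spans
    return document


def _skip_ws(text: str, pos: int) -> int:
    while pos < len(text) and text[pos].isspace():
        pos += 1
    return pos


def assign_mentions_to_sentences(document: Document,
                                 mentions: Iterable[Mention]) -> list[Mention]:
    """Return mentions with ``sentence_index`` set from the document's spans.

    A mention belongs to the sentence containing its start offset; mentions
    crossing a boundary stay with the sentence of their start.
    """
    if not document.sentences:
        raise ValueError(f"document {document.doc_id}: sentences not populated")
    starts = [s.start for s in document.sentences]
    out: list[Mention] = []
    for m in mentions:
        if m.start >= len(document.text):
            raise ValueError(
                f"document {document.doc_id}: mention offset {m.start} beyond text "
                f"length {len(document.text)}")
        idx = bisect.bisect_right(starts, m.start) - 1
        if idx < 0:
            idx = 0
        out.append(replace(m, sentence_index=document.sentences[idx].index))
    return out


def prepare_corpus(documents: list[Document],
                   mentions: list[Mention]) -> tuple[list[Document], list[Mention]]:
    """Segment every document and assign all mentions to sentences."""
    by_doc: dict[str, list[Mention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    out: list[Mention] = []
    for doc in documents:
        if not doc.sentences:
            segment_sentences(doc)
        out.extend(assign_mentions_to_sentences(doc, by_doc.get(doc.doc_id, [])))
    return documents, out


# ---------------------------------------------------------------------------
# Internal JSON-lines format
# ---------------------------------------------------------------------------


def write_jsonl(documents: Iterable[Document], mentions: Iterable[Mention],
                stream: IO[str]) -> None:
    """Write the corpus as JSON-lines, one document object per line."""
    by_doc: dict[str, list[Mention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    for doc in documents:
        obj = {
            "doc_id": doc.doc_id,
            "text": doc.text,
            "year": doc.year,
            "sentences": [[s.start, s.end] for s in doc.sentences],
            "mentions": [
                {
                    "start": m.start,
                    "end": m.end,
                    "surface": m.surface,
                    "type": m.entity_type,
                    "id": m.entity_id,
                    "sentence_index": m.sentence_index,
                }
                for m in sorted(by_doc.get(doc.doc_id, []),
                                key=lambda m: (m.start, m.end, m.entity_type))
            ],
        }
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_jsonl(stream: IO[str]) -> tuple[list[Document], list[Mention]]:
    """Read a corpus written by :func:`write_jsonl` (field-for-field inverse)."""
    documents: list[Document] = []
    mentions: list[Mention] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"line {lineno}: invalid JSON") from exc
        try:
            doc_id = obj["doc_id"]
            if doc_id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            doc = Document(
                doc_id=doc_id,
                text=obj["text"],
                year=obj.get("year"),
                sentences=[SentenceSpan(index=i, start=s, end=e)
                           for i, (s, e) in enumerate(obj.get("sentences", []))],
            )
            for m in obj.get("mentions", []):
                mentions.append(Mention(
                    doc_id=doc_id, start=m["start"], end=m["end"],
                    surface=m["surface"], entity_type=m["type"],
                    entity_id=m.get("id"), sentence_index=m.get("sentence_index")))
        except (KeyError, TypeError) as exc:
            raise CorpusFormatError(
                f"line {lineno}: schema violation in document "
                f"{obj.get('doc_id', '?')!r}: {exc}") from exc
        documents.append(doc)
    return documents, mentions
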