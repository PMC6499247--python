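"""Co-occurrence extraction and count aggregation with time-sliced snapshots.

Only grounded (post-mapping) mentions participate.  A pair co-occurs in a
sentence iff each entity has at least one grounded mention there, counted once
per sentence regardless of mention multiplicity.  Document-level co-occurrence
defaults to "the pair co-occurs in at least one sentence of the document"; the
laxer "both entities appear anywhere in the document" dialect is available via
``doc_dialect="anywhere"``.

Counts are kept per document internally so that snapshots (year cutoff,
pair-document exclusion) are exact recounts rather than approximations.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .corpus_io import Document, Mention

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    """Canonical unordered pair key (lexicographically sorted identifiers)."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CooccurrenceInstance:
    doc_id: str
    sentence_index: int
    pair: PairKey


@dataclass
class _DocRecord:
    """Per-document tallies; the unit of inclusion/exclusion for snapshots."""

    doc_id: str
    year: int
    n_sentences: int
    entity_sent: Counter = field(default_factory=Counter)  # entity -> #sentences
    pair_sent: Counter = field(default_factory=Counter)    # pair -> #sentences
    entities: set = field(default_factory=set)             # entities present (doc level)
    pairs: set = field(default_factory=set)                # pairs present (doc level)


@dataclass
class CountStats:
    """Aggregated per-year and total counts plus per-pair document postings."""

    n_sent_by_year: dict[int, int] = field(default_factory=lambda: defaultdict(int))
    n_doc_by_year: dict[int, int] = field(default_factory=lambda: defaultdict(int))
    entity_sent_by_year: dict[int, Counter] = field(default_factory=dict)
    pair_sent_by_year: dict[int, Counter] = field(default_factory=dict)
    entity_doc_by_year: dict[int, Counter] = field(default_factory=dict)
    pair_doc_by_year: dict[int, Counter] = field(default_factory=dict)
    pair_postings: dict[PairKey, set] = field(default_factory=dict)  # pair -> doc_ids
    entity_types: dict[str, str] = field(default_factory=dict)
    _docs: list[_DocRecord] = field(default_factory=list, repr=False)

    # -- totals over all years ------------------------------------------------
    @property
    def n_sent(self) -> int:
        return sum(self.n_sent_by_year.values())

    @property
    def n_doc(self) -> int:
        return sum(self.n_doc_by_year.values())

    def entity_sent_count(self, entity: str) -> int:
        return sum(c.get(entity, 0) for c in self.entity_sent_by_year.values())

    def pair_sent_count(self, a: str, b: str) -> int:
        key = pair_key(a, b)
        return sum(c.get(key, 0) for c in self.pair_sent_by_year.values())

    def entity_doc_count(self, entity: str) -> int:
        return sum(c.get(entity, 0) for c in self.entity_doc_by_year.values())

    def pair_doc_count(self, a: str, b: str) -> int:
        key = pair_key(a, b)
        return sum(c.get(key, 0) for c in self.pair_doc_by_year.values())

    def entities(self) -> set:
        out: set = set()
        for c in self.entity_sent_by_year.values():
            out.update(c)
        return out

    def pairs(self) -> set:
        out: set = set()
        for c in self.pair_sent_by_year.values():
            out.update(c)
        return out

    def _add_doc(self, rec: _DocRecord) -> None:
        y = rec.year
        self._docs.append(rec)
        self.n_sent_by_year[y] += rec.n_sentences
        self.n_doc_by_year[y] += 1
        self.entity_sent_by_year.setdefault(y, Counter()).update(rec.entity_sent)
        self.pair_sent_by_year.setdefault(y, Counter()).update(rec.pair_sent)
        self.entity_doc_by_year.setdefault(y, Counter()).update(rec.entities)
        self.pair_doc_by_year.setdefault(y, Counter()).update(rec.pairs)
        for p in rec.pairs:
            self.pair_postings.setdefault(p, set()).add(rec.doc_id)


def extract_instances(documents: Iterable[Document],
                      mentions: Iterable[Mention]) -> list[CooccurrenceInstance]:
    """List each (document, sentence, pair) co-occurrence exactly once."""
    sent_entities: dict[tuple[str, int], set] = defaultdict(set)
    for m in mentions:
        if m.entity_id is None:
            continue
        if m.sentence_index is None:
            raise ValueError(f"mention in {m.doc_id} lacks sentence_index")
        sent_entities[(m.doc_id, m.sentence_index)].add(m.entity_id)
    doc_order = {d.doc_id: i for i, d in enumerate(documents)}
    instances: list[CooccurrenceInstance] = []
    for (doc_id, sidx) in sorted(sent_entities,
                                 key=lambda k: (doc_order.get(k[0], -1), k[1])):
        ents = sorted(sent_entities[(doc_id, sidx)])
        for a, b in combinations(ents, 2):
            instances.append(CooccurrenceInstance(doc_id, sidx, (a, b)))
    return instances


def aggregate(documents: Iterable[Document], mentions: Iterable[Mention],
              doc_dialect: str = "sentence") -> CountStats:
    """Aggregate grounded mentions into per-year count statistics.

    Documents with unknown year are excluded with a logged warning count.
    ``doc_dialect`` selects how document-level co-occurrence is counted:
    ``"sentence"`` (pair within one sentence; default) or ``"anywhere"``.
    """
    if doc_dialect not in ("sentence", "anywhere"):
        raise ValueError(f"unknown doc_dialect {doc_dialect!r}")
    by_doc: dict[str, list[Mention]] = defaultdict(list)
    for m in mentions:
        by_doc[m.doc_id].append(m)

    stats = CountStats()
    skipped = 0
    for doc in documents:
        if doc.year is None:
            skipped += 1
            continue
        rec = _DocRecord(doc_id=doc.doc_id, year=doc.year,
                         n_sentences=len(doc.sentences))
        sent_entities: dict[int, set] = defaultdict(set)
        for m in by_doc.get(doc.doc_id, []):
            if m.entity_id is None:
                continue
            if m.sentence_index is None:
                raise ValueError(f"mention in {m.doc_id} lacks sentence_index")
            sent_entities[m.sentence_index].add(m.entity_id)
            stats.entity_types.setdefault(m.entity_id, m.entity_type)
        for ents in sent_entities.values():
            for e in ents:
                rec.entity_sent[e] += 1
            for a, b in combinations(sorted(ents), 2):
                rec.pair_sent[(a, b)] += 1
            rec.entities.update(ents)
        if doc_dialect == "sentence":
            rec.pairs = set(rec.pair_sent)
        else:
            rec.pairs = {p for p in combinations(sorted(rec.entities), 2)}
        stats._add_doc(rec)
    if skipped:
        logger.warning("excluded %d document(s) with unknown year", skipped)
    return stats


def snapshot(stats: CountStats, cutoff_year: Optional[int] = None,
             excluded_pair: Optional[PairKey] = None) -> CountStats:
    """Restrict counts to documents at or before ``cutoff_year``.

    When ``excluded_pair`` is given, every document in which the pair co-occurs
    (document level) is removed entirely before re-aggregation, so the pair's
    snapshot count is zero and all other counts from those documents vanish too.
    """
    blacklist: set = set()
    if excluded_pair is not None:
        key = pair_key(*excluded_pair)
        blacklist = set(stats.pair_postings.get(key, ()))
    out = CountStats(entity_types=dict(stats.entity_types))
    for rec in stats._docs:
        if cutoff_year is not None and rec.year > cutoff_year:
            continue
        if rec.doc_id in blacklist:
            continue
        out._add_doc(rec)
    return out


def write_count_tables(stats: CountStats, entity_stream, pair_stream) -> None:
    """Export per-year entity and pair count tables as TSV."""
    entity_stream.write("entity\tyear\tsentence_count\tdoc_count\n")
    for year in sorted(stats.entity_sent_by_year):
        sc = stats.entity_sent_by_year[year]
        dc = stats.entity_doc_by_year.get(year, Counter())
        for e in sorted(sc):
            entity_stream.write(f"{e}\t{year}\t{sc[e]}\t{dc.get(e, 0)}\n")
    pair_stream.write("entity_a\tentity_b\tyear\tsentence_count\tdoc_count\n")
    for year in sorted(stats.pair_sent_by_year):
        sc = stats.pair_sent_by_year[year]
        dc = stats.pair_doc_by_year.get(year, Counter())
        for (a, b) in sorted(sc):
            pair_stream.write(f"{a}\t{b}\t{year}\t{sc[(a, b)]}\t{dc.get((a, b), 0)}\n")
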