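"""String-to-identifier indexes and table-driven identifier generalization.

The string index records, for each surface string, how often it was grounded to
each identifier (and the transpose), supporting query resolution and display
labels.  Identifier mappings collapse fine-grained identifiers (e.g. per-species
gene ids) onto a shared target in a single table-driven step — no transitive
chasing, no ontology traversal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional

from .corpus_io import Mention


@dataclass
class StringIndex:
    by_string: dict[str, Counter] = field(default_factory=dict)  # surface -> {id: freq}
    by_id: dict[str, Counter] = field(default_factory=dict)      # id -> {surface: freq}

    def add(self, surface: str, entity_id: str, n: int = 1) -> None:
        self.by_string.setdefault(surface, Counter())[entity_id] += n
        self.by_id.setdefault(entity_id, Counter())[surface] += n


def build_string_index(mentions: Iterable[Mention]) -> StringIndex:
    """Index surface-string/identifier co-frequencies over grounded mentions only."""
    index = StringIndex()
    for m in mentions:
        if m.entity_id is not None:
            index.add(m.surface, m.entity_id)
    return index


def resolve_query(string: str, index: StringIndex
                  ) -> list[tuple[str, int, list[str]]]:
    """Rank candidate identifiers for a query string.

    Returns (identifier, frequency, alternative display strings) tuples sorted
    by descending frequency, ties by ascending identifier.  The alternatives are
    the identifier's other surface strings by descending frequency.  Unknown
    strings resolve to an empty list.
    """
    table = index.by_string.get(string)
    if not table:
        return []
    out = []
    for entity_id in sorted(table, key=lambda i: (-table[i], i)):
        surfaces = index.by_id[entity_id]
        alts = [s for s in sorted(surfaces, key=lambda s: (-surfaces[s], s))
                if s != string]
        out.append((entity_id, table[entity_id], alts))
    return out


def preferred_label(entity_id: str, index: StringIndex) -> str:
    """Most frequent surface string for an identifier; ties break lexicographically."""
    try:
        surfaces = index.by_id[entity_id]
    except KeyError:
        raise KeyError(f"unknown identifier {entity_id!r}") from None
    return min(surfaces, key=lambda s: (-surfaces[s], s))


@dataclass(frozen=True)
class IdMapping:
    """Single-step source->target identifier table.

    ``policy`` controls unmapped grounded identifiers: ``keep_unmapped`` (the
    default) passes them through as their own nodes; ``drop_unmapped_from_graph``
    ungrounds mentions whose type is in ``drop_types`` and whose identifier has
    no mapping, removing them from the downstream graph.
    """

    table: dict[str, str]
    policy: str = "keep_unmapped"
    drop_types: frozenset[str] = frozenset({"Gene"})

    def __post_init__(self) -> None:
        if self.policy not in ("keep_unmapped", "drop_unmapped_from_graph"):
            raise ValueError(f"unknown policy {self.policy!r}")


def read_id_mapping(stream: IO[str], policy: str = "keep_unmapped") -> IdMapping:
    """Read a two-column TSV (source_id, target_id); '#' comment lines allowed."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"mapping line {lineno}: expected 2 tab-separated columns")
        if parts[0] in table and table[parts[0]] != parts[1]:
            raise ValueError(
                f"mapping line {lineno}: conflicting targets for {parts[0]!r}")
        table[parts[0]] = parts[1]
    return IdMapping(table=table, policy=policy)


def apply_id_mapping(mentions: Iterable[Mention], mapping: IdMapping) -> list[Mention]:
    """Rewrite mention identifiers through the mapping table (applied once).

    Unmapped grounded identifiers pass through unchanged under the default
    policy; ungrounded mentions always pass through untouched.
    """
    out: list[Mention] = []
    for m in mentions:
        if m.entity_id is None:
            out.append(m)
        elif m.entity_id in mapping.table:
            out.append(replace(m, entity_id=mapping.table[m.entity_id]))
        elif (mapping.policy == "drop_unmapped_from_graph"
              and m.entity_type in mapping.drop_types):
            out.append(replace(m, entity_id=None))
        else:
            out.append(m)
    return out


def mapping_coverage(mentions: Iterable[Mention], mapping: IdMapping,
                     entity_type: Optional[str] = None) -> tuple[float, int, int]:
    """Fraction of distinct grounded source identifiers covered by the table.

    Returns (coverage, n_mapped, n_distinct); coverage is 0.0 on an empty
    identifier set.  ``entity_type`` optionally restricts to one type.
    """
    ids = {m.entity_id for m in mentions
           if m.entity_id is not None
           and (entity_type is None or m.entity_type == entity_type)}
    if not ids:
        return 0.0, 0, 0
    mapped = sum(1 for i in ids if i in mapping.table)
    return mapped / len(ids), mapped, len(ids)


def write_string_index(index: StringIndex, stream: IO[str]) -> None:
    """Export the index as TSV (string, identifier, frequency)."""
    stream.write("string\tidentifier\tfrequency\n")
    for s in sorted(index.by_string):
        table = index.by_string[s]
        for i in sorted(table, key=lambda i: (-table[i], i)):
            stream.write(f"{s}\t{i}\t{table[i]}\n")
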