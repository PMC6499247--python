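"""Synthetic annotated corpora with controlled co-occurrence structure.

Deterministic mode emits one single-sentence document per requested
co-occurrence or solo event, so aggregated counts realize the requested counts
exactly and every metric is hand-checkable.  Sampled mode draws sentence
contents from independent per-entity Bernoulli inclusion, reproducible from the
seed.  ``plant_discovery`` adds the events of an indirect A-B-C association:
strong A-B and B-C co-occurrence before a cutoff year and (optionally) the A-C
link only after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .corpus_io import Document, Mention, SentenceSpan

MODES = ("deterministic", "sampled")


@dataclass(frozen=True)
class EntitySpec:
    entity_id: str
    entity_type: str = "Chemical"
    surfaces: tuple[str, ...] = ()

    def surface(self) -> str:
        return self.surfaces[0] if self.surfaces else self.entity_id


@dataclass(frozen=True)
class Event:
    """One sentence-level co-occurrence (or solo) event, repeated ``count`` times."""

    entity_ids: tuple[str, ...]
    year: int
    count: int = 1


@dataclass
class CorpusSpec:
    entities: list[EntitySpec] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    mode: str = "deterministic"
    seed: int = 0
    default_year: int = 2000
    # sampled mode only:
    n_docs: int = 0
    inclusion_probs: dict[str, float] = field(default_factory=dict)
    sample_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    def entity_ids(self) -> set[str]:
        return {e.entity_id for e in self.entities}

    def add_pair(self, a: str, b: str, count: int, year: Optional[int] = None) -> None:
        self._check_known(a, b)
        if count < 0:
            raise ValueError("count must be non-negative")
        if count:
            self.events.append(Event((a, b), year if year is not None
                                     else self.default_year, count))

    def add_singleton(self, e: str, count: int, year: Optional[int] = None) -> None:
        self._check_known(e)
        if count < 0:
            raise ValueError("count must be non-negative")
        if count:
            self.events.append(Event((e,), year if year is not None
                                     else self.default_year, count))

    def _check_known(self, *ids: str) -> None:
        known = self.entity_ids()
        for i in ids:
            if i not in known:
                raise ValueError(f"unknown entity {i!r} referenced in events")


@dataclass(frozen=True)
class PlantedDiscovery:
    a_id: str
    b_id: str
    c_id: str
    ab_count: int
    bc_count: int
    ac_count: int = 0
    pre_cutoff_year: int = 2000
    post_cutoff_year: int = 2010

    def __post_init__(self) -> None:
        if self.ab_count <= 0 or self.bc_count <= 0:
            raise ValueError("ab_count and bc_count must be positive")
        if self.ac_count < 0:
            raise ValueError("ac_count must be non-negative")
        if self.ac_count > 0 and self.post_cutoff_year <= self.pre_cutoff_year:
            raise ValueError("post_cutoff_year must follow pre_cutoff_year "
                             "when ac events are planted")


def plant_discovery(spec: CorpusSpec, plan: PlantedDiscovery) -> CorpusSpec:
    """Add the events realizing a planted indirect association to ``spec``.

    A-B and B-C co-occurrences are dated at ``pre_cutoff_year``; A-C
    co-occurrences (if any) strictly after the cutoff.  With ``ac_count=0`` no
    generated document ever contains both A and C.
    """
    spec.add_pair(plan.a_id, plan.b_id, plan.ab_count, plan.pre_cutoff_year)
    spec.add_pair(plan.b_id, plan.c_id, plan.bc_count, plan.pre_cutoff_year)
    if plan.ac_count:
        spec.add_pair(plan.a_id, plan.c_id, plan.ac_count, plan.post_cutoff_year)
    return spec


# ---------------------------------------------------------------------------
# Corpus realization
# ---------------------------------------------------------------------------


def _make_document(doc_id: str, year: int,
                   entities: Sequence[EntitySpec]) -> tuple[Document, list[Mention]]:
    """One single-sentence document mentioning the given entities in order.

    Surface forms are embedded between filler tokens so that offset bookkeeping
    is exercised end to end.
    """
    parts: list[str] = []
    offsets: list[tuple[int, int]] = []
    text = "Study of"
    for i, e in enumerate(entities):
        text += " and " if i else " "
        start = len(text)
        text += e.surface()
        offsets.append((start, len(text)))
    text += " reported here."
    doc = Document(doc_id=doc_id, text=text, year=year,
                   sentences=[SentenceSpan(index=0, start=0, end=len(text))])
    mentions = [
        Mention(doc_id=doc_id, start=s, end=t, surface=e.surface(),
                entity_type=e.entity_type, entity_id=e.entity_id, sentence_index=0)
        for e, (s, t) in zip(entities, offsets)
    ]
    return doc, mentions


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], list[Mention]]:
    """Realize a corpus spec as (documents, mentions).

    Deterministic mode expands each event into ``count`` single-sentence
    documents; sampled mode draws ``n_docs`` sentences with independent
    Bernoulli inclusion per entity.  Output is byte-reproducible from the spec
    (and seed, in sampled mode).
    """
    by_id = {e.entity_id: e for e in spec.entities}
    documents: list[Document] = []
    mentions: list[Mention] = []
    serial = 0

    def emit(entities: Sequence[EntitySpec], year: int) -> None:
        nonlocal serial
        serial += 1
        doc, ms = _make_document(f"SYN{serial:07d}", year, entities)
        documents.append(doc)
        mentions.extend(ms)

    for ev in spec.events:
        for i in ev.entity_ids:
            if i not in by_id:
                raise ValueError(f"unknown entity {i!r} referenced in events")
        for _ in range(ev.count):
            emit([by_id[i] for i in ev.entity_ids], ev.year)

    if spec.mode == "sampled":
        rng = np.random.default_rng(spec.seed)
        ids = sorted(spec.inclusion_probs)
        unknown = [i for i in ids if i not in by_id]
        if unknown:
            raise ValueError(f"unknown entities in inclusion_probs: {unknown}")
        probs = np.array([spec.inclusion_probs[i] for i in ids])
        year = spec.sample_year if spec.sample_year is not None else spec.default_year
        for _ in range(spec.n_docs):
            included = rng.random(len(ids)) < probs
            chosen = [by_id[i] for i, inc in zip(ids, included) if inc]
            if chosen:
                emit(chosen, year)

    return documents, mentions


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def spec_from_dict(cfg: dict) -> CorpusSpec:
    spec = CorpusSpec(
        entities=[EntitySpec(entity_id=e["id"],
                             entity_type=e.get("type", "Chemical"),
                             surfaces=tuple(e.get("surfaces", ())))
                  for e in cfg.get("entities", [])],
        mode=cfg.get("mode", "deterministic"),
        seed=int(cfg.get("seed", 0)),
        default_year=int(cfg.get("default_year", 2000)),
        n_docs=int(cfg.get("n_docs", 0)),
        inclusion_probs={k: float(v)
                         for k, v in cfg.get("inclusion_probs", {}).items()},
        sample_year=cfg.get("sample_year"),
    )
    for p in cfg.get("pairs", []):
        spec.add_pair(p["a"], p["b"], int(p["count"]), p.get("year"))
    for s in cfg.get("singletons", []):
        spec.add_singleton(s["id"], int(s["count"]), s.get("year"))
    for d in cfg.get("planted", []):
        plant_discovery(spec, PlantedDiscovery(
            a_id=d["a"], b_id=d["b"], c_id=d["c"],
            ab_count=int(d["ab_count"]), bc_count=int(d["bc_count"]),
            ac_count=int(d.get("ac_count", 0)),
            pre_cutoff_year=int(d.get("pre_cutoff_year", 2000)),
            post_cutoff_year=int(d.get("post_cutoff_year", 2010))))
    return spec


def read_spec(stream) -> CorpusSpec:
    """Load a CorpusSpec from a YAML (or JSON) config stream."""
    cfg = yaml.safe_load(stream)
    if not isinstance(cfg, dict):
        raise ValueError("corpus spec must be a mapping")
    return spec_from_dict(cfg)


# ---------------------------------------------------------------------------
# Ready-made fixture: the five-node two-route example graph
# ---------------------------------------------------------------------------


def worked_example_spec() -> CorpusSpec:
    """Corpus whose count-metric graph has w(a1,b1)=10 and three edges of weight 2.

    a1 links to b1 and b2; both link to c1.  A second candidate c2 mirrors c1.
    """
    spec = CorpusSpec(entities=[
        EntitySpec("a1", "Chemical", ("alpha",)),
        EntitySpec("b1", "Gene", ("beta-one",)),
        EntitySpec("b2", "Gene", ("beta-two",)),
        EntitySpec("c1", "Disease", ("gamma-one",)),
        EntitySpec("c2", "Disease", ("gamma-two",)),
    ])
    spec.add_pair("a1", "b1", 10)
    spec.add_pair("a1", "b2", 2)
    spec.add_pair("b1", "c1", 2)
    spec.add_pair("b2", "c1", 2)
    spec.add_pair("b1", "c2", 1)
    spec.add_pair("b2", "c2", 1)
    return spec
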