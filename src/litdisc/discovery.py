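"""Open and closed discovery queries over the entity graph.

Closed discovery ranks intermediates b connecting two given nodes a and c; open
discovery ranks nodes c at distance exactly two from a.  A path (a, b, c) is
scored by an aggregation function ``fg`` over its two edge weights; in open
discovery the scores of all paths reaching one candidate are combined by an
accumulation function ``fc``.  Only two-edge paths are supported.

``discovery_oracle`` re-derives both query types by exhaustive enumeration of
all (a, b, c) triples and exists as an independent correctness check for small
graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .graph import EntityGraph
from .metrics import METRICS

AGGREGATIONS: dict[str, Callable[[float, float], float]] = {
    "min": min,
    "avg": lambda x, y: (x + y) / 2.0,
    "max": max,
    "sum": lambda x, y: x + y,
}

ACCUMULATIONS: dict[str, Callable[[list[float]], float]] = {
    "sum": sum,
    "max": max,
}

#: System defaults: Jaccard weighting, min aggregation, sum accumulation.
DEFAULT_METRIC = "jaccard"
DEFAULT_FG = "min"
DEFAULT_FC = "sum"


@dataclass(frozen=True)
class ScoringConfig:
    metric: str = DEFAULT_METRIC
    fg: str = DEFAULT_FG
    fc: str = DEFAULT_FC
    type_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.fg not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.fg!r}")
        if self.fc not in ACCUMULATIONS:
            raise ValueError(f"unknown accumulation {self.fc!r}")


@dataclass(frozen=True)
class RankedCandidate:
    entity_id: str
    rank: int
    score: float
    evidence: tuple = ()  # closed: (w_ab, w_bc); open: (n_paths,)


@dataclass
class ClosedResult:
    a: str
    c: str
    config: ScoringConfig
    candidates: list[RankedCandidate] = field(default_factory=list)


@dataclass
class OpenResult:
    a: str
    config: ScoringConfig
    candidates: list[RankedCandidate] = field(default_factory=list)


def rank_candidates(scores: dict[str, float],
                    evidence: Optional[dict[str, tuple]] = None) -> list[RankedCandidate]:
    """Order candidates by descending score, ties by ascending identifier; 1-based ranks."""
    evidence = evidence or {}
    ordered = sorted(scores, key=lambda e: (-scores[e], e))
    return [RankedCandidate(entity_id=e, rank=i, score=scores[e],
                            evidence=evidence.get(e, ()))
            for i, e in enumerate(ordered, 1)]


def _check_node(graph: EntityGraph, node: str) -> None:
    if node not in graph:
        raise KeyError(f"unknown node {node!r}")


def closed_discovery(graph: EntityGraph, a: str, c: str,
                     config: ScoringConfig = ScoringConfig()) -> ClosedResult:
    """Rank the common neighbors of a and c by fg over the two path edge weights."""
    _check_node(graph, a)
    _check_node(graph, c)
    if a == c:
        raise ValueError("closed discovery requires two distinct query nodes")
    fg = AGGREGATIONS[config.fg]
    scores: dict[str, float] = {}
    evidence: dict[str, tuple] = {}
    for b in sorted((graph.neighbors(a) & graph.neighbors(c)) - {a, c}):
        w_ab = graph.edge_weight(config.metric, a, b)
        w_bc = graph.edge_weight(config.metric, b, c)
        scores[b] = fg(w_ab, w_bc)
        evidence[b] = (w_ab, w_bc)
    return ClosedResult(a=a, c=c, config=config,
                        candidates=rank_candidates(scores, evidence))


def open_discovery(graph: EntityGraph, a: str,
                   config: ScoringConfig = ScoringConfig()) -> OpenResult:
    """Rank nodes at distance exactly two from a.

    Candidates c satisfy (a, c) not an edge, c != a, and share at least one
    neighbor with a; score(c) = fc over common neighbors b of fg(w(a,b), w(b,c)).
    """
    _check_node(graph, a)
    fg = AGGREGATIONS[config.fg]
    fc = ACCUMULATIONS[config.fc]
    direct = graph.neighbors(a)
    path_scores: dict[str, list[float]] = {}
    # sorted iteration fixes the float accumulation order, making scores
    # bit-reproducible and identical to the enumeration oracle's
    for b in sorted(direct):
        w_ab = graph.edge_weight(config.metric, a, b)
        for c in graph.neighbors(b):
            if c == a or c in direct:
                continue
            if config.type_filter is not None and \
                    graph.nodes[c].entity_type not in config.type_filter:
                continue
            w_bc = graph.edge_weight(config.metric, b, c)
            path_scores.setdefault(c, []).append(fg(w_ab, w_bc))
    scores = {c: fc(paths) for c, paths in path_scores.items()}
    evidence = {c: (len(paths),) for c, paths in path_scores.items()}
    return OpenResult(a=a, config=config,
                      candidates=rank_candidates(scores, evidence))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def discovery_oracle(graph: EntityGraph, query: tuple,
                     config: ScoringConfig = ScoringConfig()):
    """Answer a discovery query by exhaustive triple enumeration.

    ``query`` is ("open", a) or ("closed", a, c).  Intended for small graphs;
    results use the same types and the same ranking rule as the optimized
    operations, which must agree with this on every input.
    """
    mode = query[0]
    nodes = sorted(graph.nodes)
    fg = AGGREGATIONS[config.fg]
    fc = ACCUMULATIONS[config.fc]

    def weight(i: str, j: str) -> Optional[float]:
        if not graph.has_edge(i, j):
            return None
        return graph.edge_weight(config.metric, i, j)

    if mode == "closed":
        _, a, c = query
        _check_node(graph, a)
        _check_node(graph, c)
        if a == c:
            raise ValueError("closed discovery requires two distinct query nodes")
        scores: dict[str, float] = {}
        for b in nodes:
            if b in (a, c):
                continue
            w_ab, w_bc = weight(a, b), weight(b, c)
            if w_ab is None or w_bc is None:
                continue
            scores[b] = fg(w_ab, w_bc)
        return ClosedResult(a=a, c=c, config=config,
                            candidates=rank_candidates(scores))

    if mode == "open":
        _, a = query
        _check_node(graph, a)
        open_scores: dict[str, float] = {}
        for c in nodes:
            if c == a or graph.has_edge(a, c):
                continue
            if config.type_filter is not None and \
                    graph.nodes[c].entity_type not in config.type_filter:
                continue
            paths = []
            for b in nodes:
                if b in (a, c):
                    continue
                w_ab, w_bc = weight(a, b), weight(b, c)
                if w_ab is None or w_bc is None:
                    continue
                paths.append(fg(w_ab, w_bc))
            if paths:
                open_scores[c] = fc(paths)
        return OpenResult(a=a, config=config,
                          candidates=rank_candidates(open_scores))

    raise ValueError(f"unknown query mode {mode!r}")


def result_to_dict(result) -> dict:
    """JSON-serializable view of a discovery result, config included."""
    base = {
        "config": {"metric": result.config.metric, "fg": result.config.fg,
                   "fc": result.config.fc,
                   "type_filter": sorted(result.config.type_filter)
                   if result.config.type_filter else None},
        "candidates": [
            {"entity_id": c.entity_id, "rank": c.rank, "score": c.score,
             "evidence": list(c.evidence)}
            for c in result.candidates
        ],
    }
    if isinstance(result, ClosedResult):
        base["query"] = {"mode": "closed", "a": result.a, "c": result.c}
    else:
        base["query"] = {"mode": "open", "a": result.a}
    return base
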