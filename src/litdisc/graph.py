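"""Entity-level simple weighted graph over snapshot counts.

An edge exists iff the pair co-occurs in at least one sentence of the
snapshot; weights are computed lazily per metric from the edge's contingency
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Optional

from .cooccurrence import CountStats, PairKey, pair_key
from .metrics import ContingencyCounts, compute_metric


@dataclass
class NodeInfo:
    entity_id: str
    entity_type: str = "unknown"
    label: Optional[str] = None
    n_sent: int = 0
    n_doc: int = 0


@dataclass
class EntityGraph:
    """Undirected simple graph: nodes are entity identifiers, edges carry counts."""

    n_sent: int = 0
    n_doc: int = 0
    nodes: dict[str, NodeInfo] = field(default_factory=dict)
    _adj: dict[str, set] = field(default_factory=dict)
    _edges: dict[PairKey, ContingencyCounts] = field(default_factory=dict)

    # -- construction ---------------------------------------------------------
    def add_node(self, entity_id: str, entity_type: str = "unknown",
                 label: Optional[str] = None, n_sent: int = 0, n_doc: int = 0) -> None:
        self.nodes[entity_id] = NodeInfo(entity_id, entity_type, label, n_sent, n_doc)
        self._adj.setdefault(entity_id, set())

    def add_edge(self, a: str, b: str, counts: ContingencyCounts) -> None:
        key = pair_key(a, b)
        if key[0] not in self.nodes or key[1] not in self.nodes:
            raise KeyError(f"edge endpoints must be nodes: {key}")
        self._edges[key] = counts
        self._adj[key[0]].add(key[1])
        self._adj[key[1]].add(key[0])

    # -- queries --------------------------------------------------------------
    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def neighbors(self, entity_id: str) -> set:
        try:
            return set(self._adj[entity_id])
        except KeyError:
            raise KeyError(f"unknown node {entity_id!r}") from None

    def has_edge(self, a: str, b: str) -> bool:
        return pair_key(a, b) in self._edges

    def edge_counts(self, a: str, b: str) -> ContingencyCounts:
        key = pair_key(a, b)
        try:
            c = self._edges[key]
        except KeyError:
            raise KeyError(f"no edge between {a!r} and {b!r}") from None
        # counts are stored with n_a for key[0]; orient to the caller's order
        return c if (a, b) == key else c.swapped()

    def edge_weight(self, metric_name: str, a: str, b: str) -> float:
        """Metric value on the (a, b) edge; raises on absent edges (never 0-defaults)."""
        return compute_metric(metric_name, self.edge_counts(a, b))

    def edges(self):
        return self._edges.items()


def build_graph(snapshot: CountStats, labels: Optional[dict] = None,
                min_count: int = 1) -> EntityGraph:
    """Materialize the entity graph from snapshot counts.

    One node per entity with at least one grounded mention in the snapshot; one
    edge per pair with sentence co-occurrence count >= ``min_count`` (default 1,
    i.e. any co-occurrence creates an edge).
    """
    labels = labels or {}
    g = EntityGraph(n_sent=snapshot.n_sent, n_doc=snapshot.n_doc)
    for e in sorted(snapshot.entities()):
        g.add_node(e,
                   entity_type=snapshot.entity_types.get(e, "unknown"),
                   label=labels.get(e),
                   n_sent=snapshot.entity_sent_count(e),
                   n_doc=snapshot.entity_doc_count(e))
    for (a, b) in sorted(snapshot.pairs()):
        n_ab = snapshot.pair_sent_count(a, b)
        if n_ab < min_count:
            continue
        counts = ContingencyCounts(
            n_ab=n_ab,
            n_a=g.nodes[a].n_sent,
            n_b=g.nodes[b].n_sent,
            n_sent=snapshot.n_sent,
            d_ab=snapshot.pair_doc_count(a, b),
            d_a=g.nodes[a].n_doc,
            d_b=g.nodes[b].n_doc,
            n_doc=snapshot.n_doc,
        )
        g.add_edge(a, b, counts)
    return g


def write_graph(graph: EntityGraph, node_stream: IO[str], edge_stream: IO[str]) -> None:
    """Export node and edge tables as TSV."""
    node_stream.write("entity_id\ttype\tlabel\tn_sent\tn_doc\n")
    for e in sorted(graph.nodes):
        info = graph.nodes[e]
        label = info.label if info.label is not None else ""
        node_stream.write(f"{e}\t{info.entity_type}\t{label}\t{info.n_sent}\t{info.n_doc}\n")
    edge_stream.write("entity_a\tentity_b\tn_ab\td_ab\n")
    for (a, b), c in sorted(graph.edges()):
        edge_stream.write(f"{a}\t{b}\t{c.n_ab}\t{c.d_ab}\n")
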