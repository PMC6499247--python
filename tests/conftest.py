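from __future__ import annotations

import numpy as np
import pytest

from litdisc.cooccurrence import aggregate
from litdisc.fixtures import generate_corpus, worked_example_spec
from litdisc.graph import EntityGraph, build_graph
from litdisc.metrics import ContingencyCounts


@pytest.fixture(scope="session")
def worked_example_graph() -> EntityGraph:
    """Five-node graph with count weights w(a1,b1)=10 and 2 on the other c1 routes."""
    docs, mentions = generate_corpus(worked_example_spec())
    return build_graph(aggregate(docs, mentions))


def random_entity_graph(seed: int, n_nodes: int = 100,
                        edge_prob: float = 0.06) -> EntityGraph:
    """Random graph with internally consistent contingency counts.

    Per-node sentence/document counts are drawn first; each edge's joint count
    is then drawn within the bounds its margins allow, so every edge satisfies
    the count invariants against one shared corpus total.
    """
    rng = np.random.default_rng(seed)
    n_sent = 50_000
    n_doc = 20_000
    nodes = [f"E{i:03d}" for i in range(n_nodes)]
    n = {v: int(rng.integers(20, 2000)) for v in nodes}
    d = {v: max(1, n[v] // 3) for v in nodes}
    g = EntityGraph(n_sent=n_sent, n_doc=n_doc)
    types = ("Gene", "Chemical", "Disease", "Hallmark")
    for v in nodes:
        g.add_node(v, entity_type=types[int(rng.integers(len(types)))],
                   n_sent=n[v], n_doc=d[v])
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if rng.random() >= edge_prob:
                continue
            hi = min(n[a], n[b])
            n_ab = int(rng.integers(1, hi + 1))
            d_ab = min(max(1, n_ab // 3), d[a], d[b])
            c = ContingencyCounts(n_ab=n_ab, n_a=n[a], n_b=n[b], n_sent=n_sent,
                                  d_ab=d_ab, d_a=d[a], d_b=d[b], n_doc=n_doc)
            c.validate()
            g.add_edge(a, b, c)
    return g


@pytest.fixture
def random_graph() -> EntityGraph:
    return random_entity_graph(seed=7)
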