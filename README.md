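# litdisc

Literature-based discovery (LBD) over entity co-occurrence graphs.

`litdisc` builds a sentence-level co-occurrence graph from annotated
biomedical text (PubTator pipe/TSV format or an internal JSON-lines format),
scores entity associations with eight metrics, answers open- and
closed-discovery (ABC-model) queries with configurable path scoring, and
evaluates discovery replication with time-sliced corpus snapshots.

## Concepts

- **Mention vs entity** — every textual occurrence of an entity is stored with
  offsets and its grounded identifier (e.g. `PR:000003035`, `MESH:D008881`);
  the discovery graph has one node per identifier, so synonyms and homologs
  collapse onto shared nodes. Ungrounded mentions are kept in the mention data
  but never enter the graph.
- **Edges and weights** — an edge exists iff two entities co-occur in at least
  one sentence. Eight weight metrics are computed from the pair's contingency
  counts: `count`, `doc_count`, `jaccard`, `scp`, `npmi`, `chi_squared`,
  `t_test`, `llr`.
- **Discovery queries** — *closed*: given A and C, rank intermediates B
  adjacent to both, scoring each path with an aggregation function `fg`
  (`min`/`avg`/`max`/`sum`). *Open*: given A, rank nodes C at distance exactly
  two, combining path scores with an accumulation function `fc`
  (`sum`/`max`). Defaults: `jaccard`, `fg=min`, `fc=sum`.
- **Evaluation** — for each (A, B, C, year) test case the corpus is restricted
  to documents at most five years before the discovery year, every document
  where A and C co-occur is removed, and the rank of the expected node is
  measured; results are summarized as median ranks over a full
  metric × scoring-function grid.

## CLI

```sh
# synthesize a corpus from a YAML spec (see src/litdisc/data/worked_example.yaml)
litdisc generate --spec src/litdisc/data/worked_example.yaml --out corpus.jsonl

# discovery queries
litdisc query-closed --corpus corpus.jsonl --a a1 --c c1 --metric count --fg sum
litdisc query-open   --corpus corpus.jsonl --a a1            # jaccard/min/sum defaults

# real data: PubTator ingestion, identifier generalization, graph export
litdisc ingest  --input docs.pubtator --years years.tsv --out corpus.jsonl
litdisc map-ids --corpus corpus.jsonl --mapping gene2pro.tsv --out mapped.jsonl
litdisc build   --corpus mapped.jsonl --cutoff 1990 --exclude MESH:D008881,MESH:D008274 --out-dir graph/

# string -> identifier resolution, and the time-sliced evaluation grid
litdisc resolve  --corpus corpus.jsonl --string p53
litdisc evaluate --corpus corpus.jsonl --cases cases.tsv --mode open --out-dir report/
```

A YAML config file (`litdisc --config cfg.yaml ...`) supplies scoring
defaults; command-line flags win over file values. Evaluation case tables are
TSV with columns `a_id  b_id  c_id  discovery_year  mode`; two ready-made
tables of published discovery triples ship under `src/litdisc/data/`.

## Layout

```
src/litdisc/
  corpus_io.py       PubTator + JSON-lines I/O, sentence segmentation
  fixtures.py        synthetic corpora, planted A-B-C discoveries
  entity_mapping.py  string index, query resolution, id generalization
  cooccurrence.py    instance extraction, per-year counts, snapshots
  graph.py           entity graph construction and queries
  metrics.py         the eight edge-weight metrics
  discovery.py       open/closed discovery + brute-force oracle
  evaluation.py      time-sliced evaluation protocol, median ranks
  cli.py             command-line interface
```
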