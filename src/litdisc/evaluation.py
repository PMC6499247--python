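"""Time-sliced discovery evaluation: rank of the expected node, median ranks.

For each test case (A, C, optional intermediate B, discovery year) the corpus
is restricted to documents dated at most five years before the discovery and
every document where A and C co-occur is removed; the open-discovery rank of C
(resp. closed-discovery rank of B) is then measured, and results across cases
are summarized by the median rank per scoring configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Optional

from .cooccurrence import CountStats, snapshot
from .discovery import (ACCUMULATIONS, AGGREGATIONS, ScoringConfig,
                        closed_discovery, open_discovery)
from .graph import build_graph
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

CUTOFF_OFFSET_YEARS = 5

MODES = ("open", "closed", "both")


@dataclass(frozen=True)
class DiscoveryCase:
    a_id: str
    c_id: str
    discovery_year: int
    b_id: Optional[str] = None
    mode: str = "both"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("closed", "both") and not self.b_id:
            raise ValueError(
                f"case ({self.a_id}, {self.c_id}): closed mode requires b_id")

    @property
    def cutoff_year(self) -> int:
        return self.discovery_year - CUTOFF_OFFSET_YEARS


@dataclass(frozen=True)
class CaseResult:
    case: DiscoveryCase
    mode: str                 # "open" or "closed"
    rank: Optional[int]       # None = expected node not found, or case skipped
    n_candidates: int
    skipped: bool = False


def load_cases(stream: IO[str]) -> list[DiscoveryCase]:
    """Read discovery cases from TSV with columns a_id, b_id, c_id, discovery_year, mode.

    A header line is detected and skipped; b_id of "-" or empty means no
    intermediate (open-only cases).
    """
    cases: list[DiscoveryCase] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].lower() in ("a_id", "a"):
            continue
        if len(parts) < 5:
            raise ValueError(f"cases line {lineno}: expected 5 columns")
        a_id, b_id, c_id, year, mode = (p.strip() for p in parts[:5])
        if b_id in ("", "-", "—"):
            b_id = None
        try:
            cases.append(DiscoveryCase(a_id=a_id, b_id=b_id, c_id=c_id,
                                       discovery_year=int(year), mode=mode))
        except ValueError as exc:
            raise ValueError(f"cases line {lineno}: {exc}") from exc
    return cases


def evaluation_snapshot(stats: CountStats, case: DiscoveryCase) -> CountStats:
    """Counts restricted to the case's cutoff with (A, C) documents excluded."""
    return snapshot(stats, cutoff_year=case.cutoff_year,
                    excluded_pair=(case.a_id, case.c_id))


def _rank_of(target: str, candidates) -> tuple[Optional[int], int]:
    for cand in candidates:
        if cand.entity_id == target:
            return cand.rank, len(candidates)
    return None, len(candidates)


def run_case(stats: CountStats, case: DiscoveryCase, config: ScoringConfig,
             mode: Optional[str] = None) -> CaseResult:
    """Evaluate one case under one configuration.

    ``mode`` selects "open" or "closed" for cases declared "both".  Cases whose
    A node (or C node, in closed mode) is absent from the snapshot graph are
    reported as skipped.
    """
    mode = mode or case.mode
    if mode == "both":
        raise ValueError('run_case needs a single mode; pass mode="open" or "closed"')
    graph = build_graph(evaluation_snapshot(stats, case))
    if case.a_id not in graph:
        logger.warning("case (%s, %s): A node absent from snapshot graph; skipped",
                       case.a_id, case.c_id)
        return CaseResult(case, mode, rank=None, n_candidates=0, skipped=True)
    if mode == "open":
        result = open_discovery(graph, case.a_id, config)
        rank, n = _rank_of(case.c_id, result.candidates)
    else:
        if case.c_id not in graph:
            logger.warning("case (%s, %s): C node absent from snapshot graph; skipped",
                           case.a_id, case.c_id)
            return CaseResult(case, mode, rank=None, n_candidates=0, skipped=True)
        result = closed_discovery(graph, case.a_id, case.c_id, config)
        rank, n = _rank_of(case.b_id, result.candidates)
    return CaseResult(case, mode, rank=rank, n_candidates=n)


def median_rank(ranks: Iterable[Optional[int]]) -> tuple[Optional[float], int]:
    """Median of the finite ranks; returns (median, n_not_found).

    Even counts average the two middle values.  All-not-found yields
    (None, count).
    """
    finite = sorted(r for r in ranks if r is not None)
    n_missing = sum(1 for r in ranks if r is None)
    if not finite:
        return None, n_missing
    k = len(finite)
    if k % 2:
        return float(finite[k // 2]), n_missing
    return (finite[k // 2 - 1] + finite[k // 2]) / 2.0, n_missing


@dataclass
class EvaluationReport:
    """Per-configuration median ranks plus the underlying per-case results."""

    mode: str
    medians: dict[tuple[str, str, str], Optional[float]]  # (metric, fg, fc) -> median
    not_found: dict[tuple[str, str, str], int]
    case_results: dict[tuple[str, str, str], list[CaseResult]]


def grid_evaluate(stats: CountStats, cases: list[DiscoveryCase], mode: str,
                  metrics: Iterable[str] = METRIC_NAMES,
                  fgs: Iterable[str] = ("min", "avg", "max"),
                  fcs: Iterable[str] = ("sum", "max")) -> EvaluationReport:
    """Median rank for every metric x fg (x fc, open mode) combination.

    Closed-discovery scores do not involve the accumulation function, so the
    closed grid spans metrics x fgs only (fc recorded as "-").

    Per-case snapshot graphs are built once and reused across configurations.
    """
    if mode not in ("open", "closed"):
        raise ValueError(f"grid mode must be open or closed, got {mode!r}")
    selected = [c for c in cases if c.mode in (mode, "both")]
    graphs = []
    for case in selected:
        graphs.append((case, build_graph(evaluation_snapshot(stats, case))))

    fg_list = [f for f in fgs if f in AGGREGATIONS]
    fc_list = [f for f in fcs if f in ACCUMULATIONS] if mode == "open" else ["-"]
    combos = [(m, fg, fc) for m in metrics for fg in fg_list for fc in fc_list]

    medians: dict = {}
    not_found: dict = {}
    case_results: dict = {}
    for metric, fg, fc in combos:
        config = ScoringConfig(metric=metric, fg=fg,
                               fc=fc if fc != "-" else "sum")
        results: list[CaseResult] = []
        for case, graph in graphs:
            if case.a_id not in graph or (mode == "closed" and case.c_id not in graph):
                results.append(CaseResult(case, mode, None, 0, skipped=True))
                continue
            if mode == "open":
                res = open_discovery(graph, case.a_id, config)
                rank, n = _rank_of(case.c_id, res.candidates)
            else:
                res = closed_discovery(graph, case.a_id, case.c_id, config)
                rank, n = _rank_of(case.b_id, res.candidates)
            results.append(CaseResult(case, mode, rank, n))
        med, miss = median_rank([r.rank for r in results if not r.skipped])
        key = (metric, fg, fc)
        medians[key] = med
        not_found[key] = miss + sum(1 for r in results if r.skipped)
        case_results[key] = results
    return EvaluationReport(mode=mode, medians=medians, not_found=not_found,
                            case_results=case_results)


def write_report(report: EvaluationReport, stream: IO[str]) -> None:
    """TSV rendering: metrics as rows, (fg, fc) combinations as columns."""
    combos = sorted({(fg, fc) for (_, fg, fc) in report.medians})
    header = "metric\t" + "\t".join(
        f"{fc}({fg})" if fc != "-" else fg for fg, fc in combos)
    stream.write(header + "\n")
    metrics = []
    for (m, _, _) in report.medians:
        if m not in metrics:
            metrics.append(m)
    for m in metrics:
        cells = []
        for fg, fc in combos:
            med = report.medians.get((m, fg, fc))
            cells.append("NA" if med is None else
                         str(int(med)) if float(med).is_integer() else f"{med:.1f}")
        stream.write(m + "\t" + "\t".join(cells) + "\n")


def report_to_dict(report: EvaluationReport) -> dict:
    return {
        "mode": report.mode,
        "results": [
            {
                "metric": m, "fg": fg, "fc": fc,
                "median_rank": report.medians[(m, fg, fc)],
                "not_found": report.not_found[(m, fg, fc)],
                "cases": [
                    {"a": r.case.a_id, "c": r.case.c_id, "b": r.case.b_id,
                     "discovery_year": r.case.discovery_year,
                     "rank": r.rank, "n_candidates": r.n_candidates,
                     "skipped": r.skipped}
                    for r in report.case_results[(m, fg, fc)]
                ],
            }
            for (m, fg, fc) in report.medians
        ],
    }
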