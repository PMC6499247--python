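import io

import numpy as np
import pytest

from litdisc.cooccurrence import aggregate
from litdisc.discovery import ScoringConfig
from litdisc.evaluation import (DiscoveryCase, grid_evaluate,
                                evaluation_snapshot, load_cases, median_rank,
                                report_to_dict, run_case, write_report)
from litdisc.fixtures import (CorpusSpec, EntitySpec, PlantedDiscovery,
                              generate_corpus, plant_discovery)

CASES_TSV = """a_id\tb_id\tc_id\tdiscovery_year\tmode
PR:000001754\tPR:000002307\tMESH:D000236\t2010\tboth
MESH:D008881\t-\tMESH:D008274\t1988\topen
"""


class TestLoadCases:
    def test_parse(self):
        cases = load_cases(io.StringIO(CASES_TSV))
        assert cases[0] == DiscoveryCase(a_id="PR:000001754",
                                         b_id="PR:000002307",
                                         c_id="MESH:D000236",
                                         discovery_year=2010, mode="both")
        assert cases[1].b_id is None and cases[1].mode == "open"
        assert cases[0].cutoff_year == 2005

    def test_empty_file(self):
        assert load_cases(io.StringIO("")) == []

    def test_missing_b_in_closed_mode_rejected(self):
        bad = "A:1\t-\tC:1\t2000\tclosed\n"
        with pytest.raises(ValueError, match="requires b_id"):
            load_cases(io.StringIO(bad))

    def test_shipped_case_tables_parse(self):
        from importlib.resources import files
        data = files("litdisc") / "data"
        cancer = load_cases(io.StringIO(
            (data / "cancer_discoveries.tsv").read_text()))
        classic = load_cases(io.StringIO(
            (data / "classic_discoveries.tsv").read_text()))
        assert len(cancer) == 5 and all(c.mode == "both" for c in cancer)
        assert len(classic) == 5 and all(c.mode == "open" for c in classic)
        assert cancer[0].a_id == "PR:000001754"
        assert classic[0].a_id == "MESH:D008881"


def planted_stats(seed=0, n_background=50, ab=100, bc=100, ac_post=0):
    """Planted A-B-C over weaker random background associations."""
    rng = np.random.default_rng(seed)
    background = [f"N{i:03d}" for i in range(n_background)]
    spec = CorpusSpec(entities=[EntitySpec(e) for e in ["A", "B", "C"] + background])
    plant_discovery(spec, PlantedDiscovery(
        "A", "B", "C", ab_count=ab, bc_count=bc, ac_count=ac_post,
        pre_cutoff_year=2000, post_cutoff_year=2010))
    # weak random background edges, some touching A and B, dated pre-cutoff
    for i, x in enumerate(background):
        y = background[(i + 7) % n_background]
        if x != y:
            spec.add_pair(x, y, int(rng.integers(1, 6)), year=1999)
    for x in background[:20]:
        spec.add_pair("A", x, int(rng.integers(1, 6)), year=1999)
    for x in background[10:30]:
        spec.add_pair("B", x, int(rng.integers(1, 4)), year=1999)
    docs, mentions = generate_corpus(spec)
    return aggregate(docs, mentions)


@pytest.fixture(scope="module")
def planted():
    return planted_stats()


PLANTED_CASE = DiscoveryCase(a_id="A", b_id="B", c_id="C",
                             discovery_year=2005, mode="both")


class TestRunCase:
    def test_open_rank_one(self, planted):
        result = run_case(planted, PLANTED_CASE, ScoringConfig(), mode="open")
        assert result.rank == 1
        assert result.n_candidates >= 1

    def test_closed_rank_one(self, planted):
        result = run_case(planted, PLANTED_CASE, ScoringConfig(), mode="closed")
        assert result.rank == 1

    def test_exclusion_keeps_target_a_legal_candidate(self):
        # A and C also co-occur pre-cutoff: exclusion removes those documents,
        # so C stays off A's neighbor list and remains an open candidate
        base_spec = CorpusSpec(entities=[EntitySpec(e) for e in "ABC"])
        plant_discovery(base_spec, PlantedDiscovery("A", "B", "C", 50, 50))
        base_spec.add_pair("A", "C", 3, year=1998)
        docs, mentions = generate_corpus(base_spec)
        stats = aggregate(docs, mentions)
        assert stats.pair_sent_count("A", "C") == 3
        snap = evaluation_snapshot(stats, PLANTED_CASE)
        assert snap.pair_sent_count("A", "C") == 0
        result = run_case(stats, PLANTED_CASE, ScoringConfig(), mode="open")
        assert result.rank == 1

    def test_absent_a_node_skipped(self, planted, caplog):
        case = DiscoveryCase(a_id="MISSING", b_id="B", c_id="C",
                             discovery_year=2005, mode="open")
        with caplog.at_level("WARNING"):
            result = run_case(planted, case, ScoringConfig(), mode="open")
        assert result.skipped and result.rank is None

    def test_mode_both_needs_explicit_mode(self, planted):
        with pytest.raises(ValueError):
            run_case(planted, PLANTED_CASE, ScoringConfig())


class TestMedianRank:
    @pytest.mark.parametrize("ranks,expected", [
        ([5, 1, 9], 5.0),
        ([2, 4], 3.0),
        ([7], 7.0),
    ])
    def test_values(self, ranks, expected):
        med, missing = median_rank(ranks)
        assert med == expected and missing == 0

    def test_not_found_excluded_and_counted(self):
        med, missing = median_rank([3, None, 5])
        assert med == 4.0 and missing == 1

    def test_all_not_found(self):
        assert median_rank([None, None]) == (None, 2)


class TestGridEvaluate:
    def test_closed_grid_shape_and_finiteness(self, planted):
        report = grid_evaluate(planted, [PLANTED_CASE], mode="closed")
        assert len(report.medians) == 8 * 3
        assert all(m is not None for m in report.medians.values())
        assert {m for (m, _, _) in report.medians} == {
            "count", "doc_count", "jaccard", "scp", "npmi", "chi_squared",
            "t_test", "llr"}

    def test_open_grid_shape(self, planted):
        report = grid_evaluate(planted, [PLANTED_CASE], mode="open")
        assert len(report.medians) == 8 * 3 * 2

    def test_single_cell_consistent_with_run_case(self, planted):
        report = grid_evaluate(planted, [PLANTED_CASE], mode="open",
                               metrics=["jaccard"], fgs=["min"], fcs=["sum"])
        [(key, med)] = report.medians.items()
        assert key == ("jaccard", "min", "sum")
        direct = run_case(planted, PLANTED_CASE, ScoringConfig(), mode="open")
        assert med == float(direct.rank)

    def test_reproducible(self, planted):
        r1 = grid_evaluate(planted, [PLANTED_CASE], mode="open")
        r2 = grid_evaluate(planted, [PLANTED_CASE], mode="open")
        assert r1.medians == r2.medians

    def test_stronger_planting_never_worsens_rank(self):
        config = ScoringConfig(metric="count", fg="min", fc="sum")
        last_rank = None
        for ab in (20, 60, 120):
            stats = planted_stats(ab=ab, bc=ab)
            rank = run_case(stats, PLANTED_CASE, config, mode="open").rank
            assert rank is not None
            if last_rank is not None:
                assert rank <= last_rank
            last_rank = rank

    def test_report_rendering(self, planted):
        report = grid_evaluate(planted, [PLANTED_CASE], mode="open",
                               metrics=["count"], fgs=["min"], fcs=["sum"])
        buf = io.StringIO()
        write_report(report, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "metric\tsum(min)"
        assert lines[1].startswith("count\t")
        payload = report_to_dict(report)
        assert payload["mode"] == "open"
        assert payload["results"][0]["metric"] == "count"


class TestProtocolFidelity:
    def test_snapshot_has_no_post_cutoff_contribution(self, planted):
        snap = evaluation_snapshot(planted, PLANTED_CASE)
        assert all(y <= PLANTED_CASE.cutoff_year for y in snap.n_doc_by_year)
        # exhaustive recount from surviving documents
        total = sum(rec.n_sentences for rec in snap._docs)
        assert total == snap.n_sent

    def test_exclusion_exhaustive_recount(self):
        stats = planted_stats(ac_post=5)
        case = DiscoveryCase(a_id="A", b_id="B", c_id="C",
                             discovery_year=2020, mode="both")  # cutoff 2015 > ac year
        snap = evaluation_snapshot(stats, case)
        for rec in snap._docs:
            assert not ({"A", "C"} <= rec.entities)
        assert snap.pair_sent_count("A", "C") == 0
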