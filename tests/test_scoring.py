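"""Seed resolution, quotient ranking, and report serialization."""

import io

import pytest

from targetrank.graph import build_graph
from targetrank.pagerank import (
    MIN_SCALED,
    ScoreVector,
    TeleportConfig,
    personalized_pagerank,
    scale_min_to_one,
    seed_personalization,
)
from targetrank.scoring import (
    EmptySeedIntersectionError,
    RankedCandidate,
    SeedSet,
    quotient_ranking,
    read_name_map,
    read_seed_list,
    resolve_seeds,
    top_pagerank_table,
    write_report,
)
from targetrank.synthetic import degree_personalization, generate_graph, sample_seed_set

from conftest import pairs

CFG = TeleportConfig(0.0, 0.15)


def seed_set(*accs):
    return SeedSet(frozenset(accs))


class TestSeedSet:
    def test_rejects_empty_and_isoform(self):
        with pytest.raises(ValueError):
            SeedSet(frozenset())
        with pytest.raises(ValueError, match="isoform"):
            SeedSet(frozenset({"P02545-2"}))

    def test_read_seed_list_with_comments(self):
        text = "# diabetes seeds\nP02545\nQ96RG2  # PAS kinase\n\nP02545\n"
        s = read_seed_list(io.StringIO(text), provenance="test")
        assert s.accessions == {"P02545", "Q96RG2"}

    def test_read_seed_list_rejects_bad_accession(self):
        with pytest.raises(ValueError, match="not-an-acc"):
            read_seed_list(io.StringIO("not-an-acc\n"))


class TestResolveSeeds:
    def test_intersection_and_missing(self):
        g = build_graph(pairs(("A0A001", "B1B001"), ("B1B001", "C2C001")))
        eff, missing = resolve_seeds(seed_set("A0A001", "B1B001", "X9X001"), g)
        assert eff.accessions == {"A0A001", "B1B001"}
        assert missing == ["X9X001"]

    def test_all_present_gives_no_missing(self, k4_graph):
        eff, missing = resolve_seeds(seed_set(*k4_graph.vertices), k4_graph)
        assert missing == []
        assert eff.accessions == k4_graph.vertices

    def test_empty_intersection_raises(self, k4_graph):
        with pytest.raises(EmptySeedIntersectionError):
            resolve_seeds(seed_set("X9X001"), k4_graph)

    def test_planted_missing_counted(self):
        g, _ = generate_graph("erdos_renyi", 100, rng_seed=1, p=0.05)
        seeds = sample_seed_set(g, 10, rng_seed=1, planted_missing=3)
        _, missing = resolve_seeds(seeds, g)
        assert len(missing) == 3


def table2_fixture():
    """Tiny graph carrying the published scaled scores of two receptor
    proteins: degree-1 galanin receptor (397.29) and degree-2 vasopressin
    receptor (518.14)."""
    g = build_graph(pairs(("P47211", "Q00001"), ("P37288", "Q00001"), ("P37288", "Q00002")))
    scores = {"P47211": 397.29, "P37288": 518.14, "Q00001": 50.0, "Q00002": 1.0}
    return g, ScoreVector(scores, scaling=MIN_SCALED), seed_set("Q00001", "Q00002")


class TestQuotientRanking:
    def test_published_quotients(self):
        g, s, seeds = table2_fixture()
        ranked = quotient_ranking(s, g, seeds)
        by_acc = {c.accession: c for c in ranked}
        assert by_acc["P47211"].quotient == pytest.approx(397.29)
        assert by_acc["P37288"].quotient == pytest.approx(518.14 / 2)
        assert by_acc["P37288"].quotient == pytest.approx(259.07)
        assert [c.accession for c in ranked] == ["P47211", "P37288"]

    def test_quotient_times_degree_recovers_score(self):
        g, s, seeds = table2_fixture()
        for c in quotient_ranking(s, g, seeds, exclude_seeds=False):
            assert c.quotient * c.degree == pytest.approx(c.scaled_score, rel=1e-9)

    def test_ranks_are_contiguous_and_ordered(self):
        g, _ = generate_graph("preferential_attachment", 200, rng_seed=8, m=2)
        seeds = sample_seed_set(g, 15, rng_seed=8)
        s = scale_min_to_one(
            personalized_pagerank(g, seed_personalization(g, set(seeds.accessions)), CFG)
        )
        ranked = quotient_ranking(s, g, seeds)
        assert [c.rank for c in ranked] == list(range(1, len(ranked) + 1))
        for prev, nxt in zip(ranked, ranked[1:]):
            assert (prev.quotient, nxt.accession) >= (nxt.quotient, prev.accession)
            if prev.quotient != nxt.quotient:
                assert prev.quotient > nxt.quotient

    def test_seed_exclusion_preserves_relative_order(self):
        g, _ = generate_graph("erdos_renyi", 60, rng_seed=2, p=0.1)
        seeds = sample_seed_set(g, 6, rng_seed=2)
        s = scale_min_to_one(
            personalized_pagerank(g, seed_personalization(g, set(seeds.accessions)), CFG)
        )
        full = [c.accession for c in quotient_ranking(s, g, seeds, exclude_seeds=False)]
        excl = [c.accession for c in quotient_ranking(s, g, seeds, exclude_seeds=True)]
        assert [a for a in full if a not in seeds.accessions] == excl

    def test_degree_personalized_run_ties_broken_by_accession(self, k4_graph):
        s = scale_min_to_one(personalized_pagerank(k4_graph, degree_personalization(k4_graph), CFG))
        seeds = seed_set(sorted(k4_graph.vertices)[0])
        ranked = quotient_ranking(s, k4_graph, seeds, exclude_seeds=False)
        quots = [c.quotient for c in ranked]
        assert max(quots) == pytest.approx(min(quots))
        assert [c.accession for c in ranked] == sorted(k4_graph.vertices)

    def test_top_k_truncates_after_ranking(self):
        g, s, seeds = table2_fixture()
        ranked = quotient_ranking(s, g, seeds, top_k=1)
        assert len(ranked) == 1 and ranked[0].rank == 1


class TestTopPagerankTable:
    def test_first_row_is_maximum_score(self):
        g, s, seeds = table2_fixture()
        table = top_pagerank_table(s, g, seeds)
        assert table[0].accession == "P37288"
        assert table[0].scaled_score == max(s.scores.values())

    def test_k4_uniform_ordered_by_accession(self, k4_graph):
        s = scale_min_to_one(personalized_pagerank(k4_graph, degree_personalization(k4_graph), CFG))
        table = top_pagerank_table(s, k4_graph, seed_set(sorted(k4_graph.vertices)[0]))
        assert [c.accession for c in table] == sorted(k4_graph.vertices)

    def test_hub_tops_score_but_not_seed_aware_quotient(self):
        """Hub-dominated PageRank vs degree-compensated quotient: the hub
        leads by score, degree-1 seed spokes lead the retained-seed quotient
        view and push the hub out of the top 5."""
        g, man = generate_graph("hub_and_spokes", 51)
        hub = man.planted["hub_vertices"][0]
        spokes = sorted(g.vertices - {hub})
        seeds = seed_set(*spokes[:5])
        s = scale_min_to_one(
            personalized_pagerank(g, seed_personalization(g, set(seeds.accessions)), CFG)
        )
        by_score = top_pagerank_table(s, g, seeds)
        assert by_score[0].accession == hub
        by_quot = quotient_ranking(s, g, seeds, exclude_seeds=False)
        assert by_quot[0].degree == 1
        assert hub not in {c.accession for c in by_quot[:5]}


class TestReport:
    def test_empty_candidates_header_only(self):
        buf = io.StringIO()
        write_report([], buf)
        assert buf.getvalue().count("\n") == 1
        assert buf.getvalue().startswith("accession\t")

    def test_golden_three_rows(self):
        rows = [
            RankedCandidate("P47211", 397.29, 1, 397.29, 1, False),
            RankedCandidate("P37288", 518.14, 2, 259.07, 2, False),
            RankedCandidate("Q00001", 50.0, 2, 25.0, 3, True),
        ]
        buf = io.StringIO()
        write_report(rows, buf, name_map={"P47211": "galanin receptor type 1"})
        expected = (
            "accession\tscaled_pagerank\tdegree\tquotient\trank\tis_seed\tname"
            "\tscaled_pagerank_2dp\tquotient_2dp\n"
            "P47211\t397.29\t1\t397.29\t1\t0\tgalanin receptor type 1\t397.29\t397.29\n"
            "P37288\t518.14\t2\t259.07\t2\t0\t\t518.14\t259.07\n"
            "Q00001\t50.0\t2\t25.0\t3\t1\t\t50.00\t25.00\n"
        )
        assert buf.getvalue() == expected

    def test_round_trip_reproduces_quotients(self):
        g, s, seeds = table2_fixture()
        ranked = quotient_ranking(s, g, seeds)
        buf = io.StringIO()
        write_report(ranked, buf)
        lines = buf.getvalue().splitlines()
        header = lines[0].split("\t")
        for line, cand in zip(lines[1:], ranked):
            row = dict(zip(header, line.split("\t")))
            assert float(row["quotient"]) == cand.quotient
            assert float(row["scaled_pagerank"]) == cand.scaled_score

    def test_name_map_reader(self):
        names = read_name_map(io.StringIO("# map\nP47211\tgalanin receptor type 1\n"))
        assert names == {"P47211": "galanin receptor type 1"}
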