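"""ABC linking, filtering and LTC ranking, including the worked example."""

import random

import pytest

from abclbd import (
    AbcDiscovery,
    CooccurrenceMatrix,
    DiscoveryQuery,
    Vocabulary,
    VocabEntry,
    apply_filters,
    fixture_query,
    generate_c_candidates,
    link_b_terms,
    rank_by_ltc,
    run_discovery,
)
from abclbd.discovery import LinkedTermSet

from .oracles import brute_force_ltc

A = "C0018790"


def matrix_of(pairs, window=8):
    counts = {}
    for a, b, n in pairs:
        counts[tuple(sorted((a, b)))] = n
    return CooccurrenceMatrix(counts, window_size=window, n_documents=0)


def vocab_of(**cui_types):
    entries = {
        cui: VocabEntry(cui, f"term {cui}", frozenset(types), "GRP")
        for cui, types in cui_types.items()
    }
    return Vocabulary(entries)


class TestQueryValidation:
    def test_a_term_in_restriction_rejected(self):
        with pytest.raises(ValueError, match="b_restriction"):
            DiscoveryQuery(a_term=A, b_restriction=frozenset({A}))

    def test_empty_semantic_types_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            DiscoveryQuery(a_term=A, c_semantic_types=frozenset())

    @pytest.mark.parametrize("field,value", [("min_ab_count", 0), ("min_bc_count", 0)])
    def test_thresholds_must_be_positive(self, field, value):
        with pytest.raises(ValueError):
            DiscoveryQuery(a_term=A, **{field: value})


class TestLinkBTerms:
    def test_worked_example_links_17_of_19(self, worked_example, worked_query):
        matrix, _ = worked_example
        linked = link_b_terms(worked_query, matrix)
        assert len(linked.links) == 17
        assert linked.excluded == {"C2348307", "C0069409"}
        assert set(linked.links) | linked.excluded == worked_query.b_restriction

    def test_empty_restriction_gives_empty_links(self, worked_example):
        matrix, _ = worked_example
        query = DiscoveryQuery(a_term=A, b_restriction=frozenset())
        linked = link_b_terms(query, matrix)
        assert linked.links == {} and linked.excluded == frozenset()

    def test_threshold_above_every_count_excludes_all(self, worked_example, worked_query):
        matrix, _ = worked_example
        query = fixture_query(min_ab_count=10_000)
        linked = link_b_terms(query, matrix)
        assert linked.links == {}
        assert linked.excluded == worked_query.b_restriction

    def test_unrestricted_query_links_all_neighbours(self):
        matrix = matrix_of([(A, "C0000010", 3), (A, "C0000011", 1)])
        linked = link_b_terms(DiscoveryQuery(a_term=A), matrix)
        assert linked.links == {"C0000010": 3, "C0000011": 1}
        assert linked.excluded == frozenset()


class TestGenerateCCandidates:
    def test_single_chain(self):
        matrix = matrix_of([("C0000010", "C0000020", 5)])
        linked = LinkedTermSet({"C0000010": 1})
        assert generate_c_candidates(linked, matrix) == {"C0000020": {"C0000010": 5}}

    def test_merge_across_linkers(self):
        matrix = matrix_of(
            [("C0000010", "C0000020", 5), ("C0000011", "C0000020", 2)]
        )
        linked = LinkedTermSet({"C0000010": 1, "C0000011": 1})
        assert generate_c_candidates(linked, matrix) == {
            "C0000020": {"C0000010": 5, "C0000011": 2}
        }

    def test_matches_exhaustive_scan_on_random_matrix(self):
        rng = random.Random(11)
        cuis = [f"C00000{i:02d}" for i in range(20)]
        pairs = [
            (a, b, rng.randint(1, 9))
            for i, a in enumerate(cuis)
            for b in cuis[i + 1 :]
            if rng.random() < 0.3
        ]
        matrix = matrix_of(pairs)
        linked = LinkedTermSet({c: 1 for c in cuis[:5]})
        got = generate_c_candidates(linked, matrix)
        # independent scan over every concept x linker combination
        expected = {}
        for c in matrix.concepts():
            for b in linked.links:
                if b != c and matrix.pair_count(b, c) >= 1:
                    expected.setdefault(c, {})[b] = matrix.pair_count(b, c)
        assert got == expected


class TestApplyFilters:
    def test_edge_count_filter(self):
        query = DiscoveryQuery(a_term=A, min_bc_count=2)
        vocab = vocab_of(C0000020=["T047"])
        got = apply_filters(
            {"C0000020": {"C0000010": 1, "C0000011": 3}}, query, vocab
        )
        assert got == {"C0000020": {"C0000011": 3}}

    def test_target_with_no_surviving_edges_dropped(self):
        query = DiscoveryQuery(a_term=A, min_bc_count=5)
        vocab = vocab_of(C0000020=["T047"])
        assert apply_filters({"C0000020": {"C0000010": 4}}, query, vocab) == {}

    def test_semantic_type_filter(self):
        query = DiscoveryQuery(a_term=A, min_bc_count=1)
        vocab = vocab_of(C0000020=["T121"], C0000021=["T047", "T121"])
        got = apply_filters(
            {"C0000020": {"C0000010": 3}, "C0000021": {"C0000010": 3}}, query, vocab
        )
        assert set(got) == {"C0000021"}

    def test_unknown_vocab_target_dropped(self):
        query = DiscoveryQuery(a_term=A, min_bc_count=1)
        assert apply_filters({"C0000020": {"C0000010": 3}}, query, Vocabulary({})) == {}

    def test_count_2_edge_survives_default_filter(self, worked_example, worked_query):
        """The weakest printed edges (count 2) sit exactly at the default cutoff."""
        matrix, vocab = worked_example
        linked = link_b_terms(worked_query, matrix)
        candidates = generate_c_candidates(linked, matrix)
        got = apply_filters(candidates, worked_query, vocab, matrix)
        assert got["C0043194"]["C0028375"] == 2  # norleucine edge retained

    def test_keep_direct_false_drops_directly_cooccurring_targets(self):
        matrix = matrix_of([(A, "C0000010", 2), ("C0000010", "C0000020", 3), (A, "C0000020", 1)])
        vocab = vocab_of(C0000020=["T047"])
        candidates = {"C0000020": {"C0000010": 3}}
        keep = apply_filters(
            candidates, DiscoveryQuery(a_term=A, keep_direct=True), vocab, matrix
        )
        drop = apply_filters(
            candidates, DiscoveryQuery(a_term=A, keep_direct=False), vocab, matrix
        )
        assert set(keep) == {"C0000020"} and drop == {}


class TestRankByLtc:
    def test_worked_example_scores_and_breakdowns(self, worked_example, worked_query):
        matrix, vocab = worked_example
        result = run_discovery(worked_query, matrix, vocab)
        fisheye = result.hypothesis_for("C0342895")
        assert fisheye.ltc == 15
        assert fisheye.b_breakdown[0] == ("C0556150", 503)
        wiskott = result.hypothesis_for("C0043194")
        assert wiskott.ltc == 14
        assert wiskott.b_breakdown[0] == ("C0019602", 508)

    def test_breakdown_ties_broken_by_cui(self, worked_example, worked_query):
        matrix, vocab = worked_example
        result = run_discovery(worked_query, matrix, vocab)
        tail = result.hypothesis_for("C0043194").b_breakdown[-3:]
        assert [b for b, _ in tail] == ["C0028375", "C0058624", "C0070662"]
        assert all(n == 2 for _, n in tail)

    def test_single_candidate_single_link(self):
        hyps = rank_by_ltc({"C0000020": {"C0000010": 4}})
        assert len(hyps) == 1
        assert hyps[0].ltc == 1 and hyps[0].c_term == "C0000020"

    def test_matches_brute_force_recount_on_random_instance(self):
        rng = random.Random(5)
        candidates = {
            f"C00002{i:02d}": {
                f"C00001{j:02d}": rng.randint(2, 9)
                for j in range(rng.randint(1, 8))
            }
            for i in range(15)
        }
        hyps = rank_by_ltc(candidates)
        expected = brute_force_ltc(candidates)
        assert {h.c_term: h.ltc for h in hyps} == expected
        scores = [h.ltc for h in hyps]
        assert scores == sorted(scores, reverse=True)
        for first, second in zip(hyps, hyps[1:]):
            if first.ltc == second.ltc:
                assert first.c_term < second.c_term


class TestRunDiscovery:
    def test_worked_example_full_ranking(self, worked_example, worked_query):
        matrix, vocab = worked_example
        result = run_discovery(worked_query, matrix, vocab)
        assert [h.c_term for h in result.hypotheses] == [A, "C0342895", "C0043194"]
        assert result.ltc(A) == 17  # start term tops its own ranking

    def test_empty_matrix_gives_empty_result(self, worked_example, worked_query):
        _, vocab = worked_example
        empty = CooccurrenceMatrix({}, 8, 0)
        result = run_discovery(worked_query, empty, vocab)
        assert result.hypotheses == ()

    def test_unknown_a_term_warns_but_runs(self, worked_example, caplog):
        matrix, vocab = worked_example
        query = fixture_query(a_term="C7777777")
        with caplog.at_level("WARNING"):
            result = run_discovery(query, matrix, vocab)
        assert result.hypotheses == ()
        assert any("vocabulary" in r.message for r in caplog.records)

    def test_ltc_bounded_by_linker_count(self, worked_example, worked_query):
        matrix, vocab = worked_example
        result = run_discovery(worked_query, matrix, vocab)
        for h in result.hypotheses:
            assert 0 < h.ltc <= len(result.linked)

    @pytest.mark.parametrize("field", ["min_ab_count", "min_bc_count"])
    def test_filter_monotonicity(self, worked_example, field):
        """Raising either threshold never raises any LTC or adds a hypothesis."""
        matrix, vocab = worked_example
        baseline = run_discovery(fixture_query(), matrix, vocab)
        for value in (2, 3, 10, 1000):
            stricter = run_discovery(fixture_query(**{field: value}), matrix, vocab)
            assert len(stricter.hypotheses) <= len(baseline.hypotheses)
            for h in stricter.hypotheses:
                assert h.ltc <= baseline.ltc(h.c_term)

    def test_ranking_invariant_under_document_order(self):
        from abclbd import Corpus, count_cooccurrences
        from abclbd.synthetic import plant_abc_scenario

        scenario = plant_abc_scenario(4, [4, 2], seed=3)
        docs = scenario.corpus.documents
        relabeled = Corpus(
            tuple(
                type(d)(f"x{i}", d.tokens)
                for i, d in enumerate(reversed(docs))
            )
        )
        r1 = run_discovery(
            scenario.query, count_cooccurrences(scenario.corpus, 8), scenario.vocab
        )
        r2 = run_discovery(scenario.query, count_cooccurrences(relabeled, 8), scenario.vocab)
        assert [(h.c_term, h.ltc) for h in r1.hypotheses] == [
            (h.c_term, h.ltc) for h in r2.hypotheses
        ]


class TestModelObject:
    def test_fit_matches_functional_pipeline(self, worked_example, worked_query):
        matrix, vocab = worked_example
        model = AbcDiscovery(matrix, vocab)
        assert model.fit(worked_query) == run_discovery(worked_query, matrix, vocab)

    def test_refit_with_changed_threshold(self, worked_example, worked_query):
        matrix, vocab = worked_example
        model = AbcDiscovery(matrix, vocab)
        result = model.fit(worked_query)
        stricter = model.refit(result, min_bc_count=5)
        assert stricter.query.min_bc_count == 5
        assert stricter.ltc("C0043194") < result.ltc("C0043194")

    def test_summary_contains_ranked_header(self, worked_example, worked_query):
        matrix, vocab = worked_example
        summary = AbcDiscovery(matrix, vocab).fit(worked_query).summary()
        assert "15 - C0342895 - Disease, fish-eye" in summary
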