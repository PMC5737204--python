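"""Span matching, agreement matrices and P/R/F metrics."""

from random import Random

import pytest
from hypothesis import given, strategies as st

from annokit.agreement import (
    UNMATCHED,
    AgreementMatrix,
    MatchConfig,
    MatchMode,
    build_agreement_matrix,
    compute_iaa,
    compute_ira,
    match_entity_sets,
    match_relation_sets,
    multi_annotator_summary,
    percent,
    prf_from_counts,
    span_overlap,
)
from annokit.model import Granularity, ValidationError
from helpers import (
    aset,
    brute_force_max_matching,
    doc,
    drel,
    ent,
    mrel,
    random_entity_sets,
)

RELAXED = MatchConfig(mode=MatchMode.RELAXED, min_overlap=1)
EXACT = MatchConfig(mode=MatchMode.EXACT)


class TestSpanOverlap:
    @pytest.mark.parametrize(
        "a_spans, b_spans, expected",
        [
            ([(0, 5)], [(3, 8)], 2),
            ([(0, 5)], [(0, 5)], 5),
            ([(0, 5)], [(5, 9)], 0),
            # discontinuous: per-character intersection count = 1 + 2
            ([(0, 3), (10, 14)], [(2, 12)], 3),
        ],
    )
    def test_overlap_is_summed_fragment_intersection(self, a_spans, b_spans, expected):
        d = doc()
        assert span_overlap(ent("A", a_spans, document=d), ent("B", b_spans, document=d)) == expected

    def test_cross_document_overlap_is_an_error(self):
        a = ent("A", (0, 5), document=doc("d1"))
        b = ent("B", (0, 5), document=doc("d2"))
        with pytest.raises(ValidationError):
            span_overlap(a, b)


class TestEntityMatching:
    def test_exact_identical_spans_pair(self):
        d = doc()
        res = match_entity_sets(
            [ent("A1", (0, 3), "Chem", document=d)],
            [ent("B1", (0, 3), "Chem", document=d)],
            EXACT,
        )
        assert len(res.pairs) == 1 and not res.unmatched_a and not res.unmatched_b

    def test_relaxed_threshold_boundary(self):
        d = doc()
        A, B = [ent("A1", (0, 5), document=d)], [ent("B1", (3, 8), document=d)]
        k2 = match_entity_sets(A, B, MatchConfig(mode="relaxed", min_overlap=2))
        k3 = match_entity_sets(A, B, MatchConfig(mode="relaxed", min_overlap=3))
        assert [(a, b, o) for a, b, o in k2.pairs] == [("A1", "B1", 2)]
        assert k3.pairs == [] and k3.unmatched_a == ["A1"]

    def test_relaxed_attains_exhaustive_maximum_on_competing_spans(self):
        d = doc()
        A = [ent("A1", (0, 10), document=d), ent("A2", (0, 4), document=d)]
        B = [ent("B1", (2, 6), document=d)]
        res = match_entity_sets(A, B, MatchConfig(mode="relaxed", min_overlap=2))
        assert len(res.pairs) == brute_force_max_matching(A, B, 2) == 1

    def test_exact_duplicates_match_one_to_one(self):
        d = doc()
        A = [ent("A1", (0, 3), document=d), ent("A2", (0, 3), document=d)]
        B = [ent("B1", (0, 3), document=d)]
        res = match_entity_sets(A, B, EXACT)
        assert len(res.pairs) == 1 and len(res.unmatched_a) == 1

    def test_mixed_documents_rejected(self):
        with pytest.raises(ValidationError):
            match_entity_sets(
                [ent("A1", (0, 3), document=doc("d1"))],
                [ent("B1", (0, 3), document=doc("d2"))],
                EXACT,
            )

    @pytest.mark.parametrize("seed", range(30))
    def test_relaxed_count_matches_brute_force(self, seed):
        rng = Random(9000 + seed)
        A, B = random_entity_sets(rng)
        k = rng.randint(1, 4)
        res = match_entity_sets(A, B, MatchConfig(mode="relaxed", min_overlap=k))
        assert len(res.pairs) == brute_force_max_matching(A, B, k)

    @pytest.mark.parametrize("seed", range(15))
    def test_relaxed_pair_count_monotone_in_min_overlap(self, seed):
        rng = Random(500 + seed)
        A, B = random_entity_sets(rng)
        counts = [
            len(match_entity_sets(A, B, MatchConfig(mode="relaxed", min_overlap=k)).pairs)
            for k in range(1, 8)
        ]
        assert counts == sorted(counts, reverse=True)
        exact_pairs = len(match_entity_sets(A, B, EXACT).pairs)
        assert exact_pairs <= counts[0]


class TestRelationMatching:
    def test_document_level_identical_pair_on_diagonal(self):
        a = [drel("RA", "Effect", [("aspirin", "Chemical"), ("ulcer", "Disease")], annotator="a")]
        b = [drel("RB", "Effect", [("aspirin", "Chemical"), ("ulcer", "Disease")], annotator="b")]
        res = match_relation_sets(a, b, [], [], match_entity_sets([], [], EXACT),
                                  Granularity.DOCUMENT)
        m = build_agreement_matrix(res, a, b)
        assert m.tp("Effect") == 1

    def test_retyped_relation_still_pairs_off_diagonal(self):
        a = [drel("RA", "Effect", [("aspirin", "Chemical"), ("ulcer", "Disease")])]
        b = [drel("RB", "Hypothetical", [("aspirin", "Chemical"), ("ulcer", "Disease")])]
        res = match_relation_sets(a, b, [], [], match_entity_sets([], [], EXACT),
                                  Granularity.DOCUMENT)
        m = build_agreement_matrix(res, a, b)
        assert m.cell("Effect", "Hypothetical") == 1
        assert m.tp("Effect") == 0 and m.fp("Effect") == 1

    def test_unmatched_participant_propagates_to_relation(self):
        d = doc()
        ea = [ent("A1", (0, 3), document=d), ent("A2", (10, 14), document=d)]
        eb = [ent("B2", (10, 14), document=d)]  # A1's counterpart missing
        ematch = match_entity_sets(ea, eb, EXACT)
        ra = [mrel("RA", "Effect", ("A1", "A2"))]
        res = match_relation_sets(ra, [], ea, eb, ematch, Granularity.MENTION)
        assert res.unmatched_a == ["RA"]

    def test_undirected_type_accepts_swapped_roles(self):
        d = doc()
        ea = [ent("A1", (0, 3), document=d), ent("A2", (10, 14), document=d)]
        eb = [ent("B1", (0, 3), document=d), ent("B2", (10, 14), document=d)]
        ematch = match_entity_sets(ea, eb, EXACT)
        ra = [mrel("RA", "Binds", ("A1", "A2"))]
        rb = [mrel("RB", "Binds", ("B2", "B1"))]
        directed = match_relation_sets(ra, rb, ea, eb, ematch, Granularity.MENTION)
        undirected = match_relation_sets(
            ra, rb, ea, eb, ematch, Granularity.MENTION, is_directed=lambda t: False
        )
        assert directed.pairs == [] and len(undirected.pairs) == 1


class TestMatrixAndMetrics:
    def test_margins_reproduce_side_totals(self):
        d = doc()
        A = [ent("A1", (0, 3), "X", document=d), ent("A2", (4, 8), "X", document=d),
             ent("A3", (9, 12), "Y", document=d)]
        B = [ent("B1", (0, 3), "X", document=d), ent("B2", (4, 8), "Y", document=d)]
        m = build_agreement_matrix(match_entity_sets(A, B, EXACT), A, B)
        assert m.total_a() == 3 and m.total_b() == 2
        assert m.row_sum("X") == 2  # both X annotations of A accounted for
        assert m.cell("X", "Y") == 1 and m.cell("Y", UNMATCHED) == 1

    def test_empty_sides_give_empty_matrix(self):
        m = build_agreement_matrix(match_entity_sets([], [], EXACT), [], [])
        assert m.cells == {}

    def test_contingency_triple_rounds_to_published_percents(self):
        m = prf_from_counts(762, 263, 237)
        assert m.as_percents() == (74, 76, 75)
        assert m.precision == pytest.approx(762 / 1025)
        assert m.f_score == pytest.approx(0.75296, abs=1e-4)

    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (0, 5, 0, (0.0, 0.0, 0.0)),
            (10, 0, 0, (1.0, 1.0, 1.0)),
            (0, 0, 0, (1.0, 1.0, 1.0)),  # agreement on nothing is agreement
            (0, 0, 7, (0.0, 0.0, 0.0)),
        ],
    )
    def test_degenerate_denominator_conventions(self, tp, fp, fn, expected):
        m = prf_from_counts(tp, fp, fn)
        assert (m.precision, m.recall, m.f_score) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf_from_counts(-1, 0, 0)

    def test_percent_rounds_half_up(self):
        assert percent(0.745) == 75
        assert percent(0.7434) == 74

    @given(st.integers(0, 400), st.integers(0, 400), st.integers(0, 400))
    def test_f_between_precision_and_recall(self, tp, fp, fn):
        m = prf_from_counts(tp, fp, fn)
        lo, hi = sorted((m.precision, m.recall))
        assert lo - 1e-12 <= m.f_score <= hi + 1e-12


class TestCorpusAgreement:
    def test_identical_sets_reach_perfect_agreement(self, two_annotator_project):
        from annokit.model import copy_annotations

        p = two_annotator_project
        copy_annotations(p, 1, "Jane", "John", overwrite=True)
        ents, rels = compute_iaa(p, 1, "Jane", "John", EXACT)
        assert ents.overall.f_score == 1.0 and rels.overall.f_score == 1.0

    def test_subset_annotator_hand_count(self, two_annotator_project):
        # Jane has 3 entities, John the same 2 of them: p = 2/3, r = 1
        ents, _rels = compute_iaa(two_annotator_project, 1, "Jane", "John", EXACT)
        assert ents.overall.precision == pytest.approx(2 / 3)
        assert ents.overall.recall == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_swapping_sides_transposes_matrix_and_swaps_p_r(self, seed):
        rng = Random(42 + seed)
        A, B = random_entity_sets(rng, max_per_side=8)
        cfg = MatchConfig(mode="relaxed", min_overlap=rng.randint(1, 3))
        m_ab = build_agreement_matrix(match_entity_sets(A, B, cfg), A, B)
        m_ba = build_agreement_matrix(match_entity_sets(B, A, cfg), B, A)
        assert m_ab.cells == m_ba.transposed().cells
        from annokit.agreement import report_from_matrix

        r_ab = report_from_matrix(m_ab, "entities", ("a", "b"))
        r_ba = report_from_matrix(m_ba, "entities", ("b", "a"))
        assert r_ab.overall.precision == pytest.approx(r_ba.overall.recall, abs=1e-12)
        assert r_ab.overall.recall == pytest.approx(r_ba.overall.precision, abs=1e-12)
        assert abs(r_ab.overall.f_score - r_ba.overall.f_score) < 1e-12

    def test_ira_retype_lands_off_diagonal(self, two_annotator_project):
        p = two_annotator_project
        from annokit.model import create_round

        create_round(p)
        # round 2 = round 1 with one relation re-typed Effect -> Hypothetical
        r2_set = p.sets[("Jane", 2)]
        import copy as _copy

        r2_set.entities = _copy.deepcopy(p.sets[("Jane", 1)].entities)
        r2_set.relations = _copy.deepcopy(p.sets[("Jane", 1)].relations)
        for a in r2_set.entities + r2_set.relations:
            a.round = 2
        r2_set.relations[0].rtype = "Hypothetical"
        _ents, rels = compute_ira(p, "Jane", 1, 2, EXACT)
        assert rels.matrix.cell("Hypothetical", "Effect") == 1
        assert rels.overall.f_score == 0.0  # the single relation disagrees on type

    def test_ira_new_annotations_inflate_precision_side_fp(self, two_annotator_project):
        p = two_annotator_project
        from annokit.model import create_round

        create_round(p)
        d = p.documents["d1"]
        later = p.sets[("Jane", 2)]
        import copy as _copy

        later.entities = _copy.deepcopy(p.sets[("Jane", 1)].entities)
        for e in later.entities:
            e.round = 2
        later.entities.append(
            ent("E99", (33, 40), "Chem", document=d, annotator="Jane", round=2)
        )
        ents, _ = compute_ira(p, "Jane", 1, 2, EXACT)
        assert ents.overall.fp == 1 and ents.overall.fn == 0

    def test_unchanged_rounds_have_f_one(self, two_annotator_project):
        p = two_annotator_project
        from annokit.model import duplicate_round

        r2 = duplicate_round(p, 1)
        ents, rels = compute_ira(p, "Jane", 1, r2, EXACT)
        assert ents.overall.f_score == 1.0 and rels.overall.f_score == 1.0

    def test_multi_annotator_macro_average(self, two_annotator_project):
        p = two_annotator_project
        summary = multi_annotator_summary(p, 1, EXACT)
        assert len(summary.pairwise) == 1
        (pair, ents, _rels) = summary.pairwise[0]
        assert pair == ("Jane", "John")
        assert summary.macro_f_entities == pytest.approx(ents.overall.f_score)

    def test_three_identical_sets_macro_one(self, two_annotator_project):
        from annokit.model import copy_annotations

        p = two_annotator_project
        p.annotators.append("Jo")
        copy_annotations(p, 1, "Jane", "John", overwrite=True)
        copy_annotations(p, 1, "Jane", "Jo", overwrite=True)
        summary = multi_annotator_summary(p, 1, EXACT)
        assert len(summary.pairwise) == 3
        assert summary.macro_f_entities == 1.0 and summary.macro_f_relations == 1.0

    def test_single_annotator_summary_rejected(self, two_annotator_project):
        p = two_annotator_project
        del p.sets[("John", 1)]
        with pytest.raises(ValidationError):
            multi_annotator_summary(p, 1, EXACT)
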