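"""Clustering, support thresholds and manual overrides."""

from random import Random

import pytest

from annokit.agreement import MatchConfig
from annokit.consensus import (
    ConsensusConfig,
    Override,
    build_consensus,
    cluster_annotations,
    overrides_from_table,
    review_table,
)
from annokit.model import ValidationError
from helpers import aset, doc, drel, ent, entity_keys, mrel

EXACT = MatchConfig(mode="exact")
RELAXED2 = MatchConfig(mode="relaxed", min_overlap=2)


def _sets_from_spans(spans_by_annotator, d=None, etype="T"):
    d = d or doc()
    sets = []
    for annotator, spans in spans_by_annotator.items():
        sets.append(
            aset(
                annotator,
                entities=[
                    ent(f"E{i}", span, etype, document=d, annotator=annotator)
                    for i, span in enumerate(spans, 1)
                ],
            )
        )
    return sets


class TestClustering:
    def test_identical_entities_form_one_cluster(self):
        sets = _sets_from_spans({"a": [(0, 5)], "b": [(0, 5)]})
        clusters = cluster_annotations(sets, EXACT)
        assert len(clusters) == 1 and clusters[0].support == 2

    def test_relaxed_single_linkage_by_hand(self):
        # a (0,5) and b (3,8) overlap by 2; c (20,25) is isolated
        sets = _sets_from_spans({"a": [(0, 5)], "b": [(3, 8)], "c": [(20, 25)]})
        clusters = cluster_annotations(sets, RELAXED2)
        supports = sorted(c.support for c in clusters)
        assert supports == [1, 2]

    def test_exact_with_required_type_splits_type_disagreement(self):
        d = doc()
        sets = [
            aset("a", entities=[ent("E1", (0, 5), "Chem", document=d, annotator="a")]),
            aset("b", entities=[ent("E1", (0, 5), "Drug", document=d, annotator="b")]),
        ]
        strict = MatchConfig(mode="exact", require_type_for_match=True)
        assert len(cluster_annotations(sets, strict)) == 2
        assert len(cluster_annotations(sets, EXACT)) == 1

    def test_sets_from_different_rounds_rejected(self):
        d = doc()
        sets = [
            aset("a", 1, [ent("E1", (0, 5), document=d, annotator="a")]),
            aset("b", 2, [ent("E1", (0, 5), document=d, annotator="b", round=2)]),
        ]
        with pytest.raises(ValidationError):
            cluster_annotations(sets, EXACT)

    def test_relation_clusters_require_type_equality(self):
        d = doc()
        sets = []
        for annotator, rtype in (("a", "Effect"), ("b", "Hypothetical")):
            e = ent("E1", (0, 5), document=d, annotator=annotator)
            e2 = ent("E2", (11, 15), document=d, annotator=annotator)
            sets.append(aset(annotator, entities=[e, e2],
                             relations=[mrel("R1", rtype, ("E1", "E2"), annotator=annotator)]))
        clusters = cluster_annotations(sets, EXACT)
        rel_clusters = [c for c in clusters if c.kind == "relation"]
        assert len(rel_clusters) == 2
        assert all(c.support == 1 for c in rel_clusters)


class TestThresholds:
    def test_half_threshold_with_two_annotators_is_union(self):
        sets = _sets_from_spans({"a": [(0, 5), (10, 15)], "b": [(0, 5), (20, 25)]})
        clusters = cluster_annotations(sets, EXACT)
        out = build_consensus(clusters, ConsensusConfig(threshold=0.5, match=EXACT), 2, round=1)
        assert len(out.entities) == 3  # union of distinct spans

    def test_threshold_one_is_intersection(self):
        sets = _sets_from_spans({"a": [(0, 5), (10, 15)], "b": [(0, 5), (20, 25)]})
        clusters = cluster_annotations(sets, EXACT)
        out = build_consensus(clusters, ConsensusConfig(threshold=1.0, match=EXACT), 2, round=1)
        assert [e.span_signature() for e in out.entities] == [((0, 5),)]

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_in_threshold_and_limit_semantics(self, seed):
        rng = Random(700 + seed)
        d = doc()
        spans_by = {}
        pool = [(i * 7, i * 7 + rng.randint(2, 6)) for i in range(8)]
        for annotator in ("a", "b", "c"):
            spans_by[annotator] = sorted(rng.sample(pool, rng.randint(1, 7)))
        sets = _sets_from_spans(spans_by, d)
        clusters = cluster_annotations(sets, EXACT)
        sizes = []
        for t in (0.01, 1 / 3, 0.5, 2 / 3, 1.0):
            out = build_consensus(clusters, ConsensusConfig(threshold=t, match=EXACT), 3)
            sizes.append(len(out.entities))
        assert sizes == sorted(sizes, reverse=True)
        union = set().union(*(set(s) for s in spans_by.values()))
        inter = set.intersection(*(set(s) for s in spans_by.values()))
        assert sizes[0] == len(union)
        assert sizes[-1] == len(inter)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ConsensusConfig(threshold=0.0)
        with pytest.raises(ValueError):
            ConsensusConfig(threshold=1.5)


class TestOverridesAndRepresentatives:
    def test_force_exclude_beats_unanimous_support(self):
        # both annotators marked it, the adjudicator still rejects it
        sets = _sets_from_spans({"a": [(0, 5)], "b": [(0, 5)]})
        clusters = cluster_annotations(sets, EXACT)
        cid = clusters[0].cluster_id
        cfg = ConsensusConfig(
            threshold=0.5, match=EXACT, overrides={cid: Override.FORCE_EXCLUDE}
        )
        assert build_consensus(clusters, cfg, 2).entities == []

    def test_force_include_rescues_minority_annotation(self):
        sets = _sets_from_spans({"a": [(0, 5)], "b": [(10, 15)], "c": [(10, 15)]})
        clusters = cluster_annotations(sets, EXACT)
        minority = next(c for c in clusters if c.support == 1)
        cfg = ConsensusConfig(
            threshold=2 / 3, match=EXACT,
            overrides={minority.cluster_id: Override.FORCE_INCLUDE},
        )
        out = build_consensus(clusters, cfg, 3)
        assert len(out.entities) == 2

    def test_representative_is_majority_shape(self):
        d = doc()
        sets = [
            aset("a", entities=[ent("E1", (0, 5), document=d, annotator="a")]),
            aset("b", entities=[ent("E1", (0, 6), document=d, annotator="b")]),
            aset("c", entities=[ent("E1", (0, 5), document=d, annotator="c")]),
        ]
        clusters = cluster_annotations(sets, MatchConfig(mode="relaxed", min_overlap=1))
        out = build_consensus(clusters, ConsensusConfig(threshold=0.5), 3)
        assert out.entities[0].span_signature() == ((0, 5),)

    def test_orphaned_relations_dropped(self):
        d = doc()
        # relation endpoint E2 only annotated by 'a' -> fails 2/2 threshold
        a = aset("a",
                 entities=[ent("E1", (0, 5), document=d, annotator="a"),
                           ent("E2", (11, 15), document=d, annotator="a")],
                 relations=[mrel("R1", "Effect", ("E1", "E2"), annotator="a")])
        b = aset("b",
                 entities=[ent("E1", (0, 5), document=d, annotator="b"),
                           ent("E2", (11, 15), document=d, annotator="b")],
                 relations=[mrel("R1", "Effect", ("E1", "E2"), annotator="b")])
        b.entities.pop()  # drop b's E2 -> but then b's relation dangles; drop it too
        b.relations.clear()
        clusters = cluster_annotations([a, b], EXACT)
        out = build_consensus(clusters, ConsensusConfig(threshold=1.0), 2)
        assert len(out.entities) == 1 and out.relations == []

    def test_consensus_relations_reference_consensus_entities(self):
        d = doc()
        sets = []
        for annotator in ("a", "b"):
            e1 = ent("E1", (0, 5), document=d, annotator=annotator)
            e2 = ent("E2", (11, 15), document=d, annotator=annotator)
            sets.append(aset(annotator, entities=[e1, e2],
                             relations=[mrel("R1", "Effect", ("E1", "E2"), annotator=annotator)]))
        clusters = cluster_annotations(sets, EXACT)
        out = build_consensus(clusters, ConsensusConfig(threshold=1.0), 2)
        out.validate()  # refs resolve inside the consensus set
        assert len(out.relations) == 1

    def test_consensus_of_identical_sets_equals_any_one(self):
        d = doc()
        sets = _sets_from_spans({"a": [(0, 5), (10, 15)], "b": [(0, 5), (10, 15)],
                                 "c": [(0, 5), (10, 15)]}, d)
        clusters = cluster_annotations(sets, EXACT)
        for t in (0.2, 0.5, 1.0):
            out = build_consensus(clusters, ConsensusConfig(threshold=t), 3)
            assert entity_keys(out.entities) == entity_keys(sets[0].entities)

    def test_review_table_round_trips_overrides(self):
        sets = _sets_from_spans({"a": [(0, 5)], "b": [(0, 5)]})
        clusters = cluster_annotations(sets, EXACT)
        cfg = ConsensusConfig(threshold=0.5)
        table = review_table(clusters, cfg, 2)
        edited = table.replace("include", Override.FORCE_EXCLUDE.value, 1)
        overrides = overrides_from_table(edited)
        assert overrides == {clusters[0].cluster_id: Override.FORCE_EXCLUDE}

    def test_document_level_relation_consensus(self):
        sets = [
            aset("a", relations=[drel("R1", "Effect",
                 [("aspirin", "Chem"), ("ulcer", "Dis")], annotator="a")]),
            aset("b", relations=[drel("R1", "Effect",
                 [("ulcer", "Dis"), ("aspirin", "Chem")], annotator="b")]),
        ]
        clusters = cluster_annotations(sets, EXACT)
        rel = [c for c in clusters if c.kind == "relation"]
        assert len(rel) == 1 and rel[0].support == 2
        out = build_consensus(clusters, ConsensusConfig(threshold=1.0), 2)
        assert len(out.relations) == 1
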