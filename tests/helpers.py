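"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations
from random import Random

from annokit.model import (
    AnnotatedDocument,
    AnnotationSet,
    EntityAnnotation,
    Fragment,
    Granularity,
    Origin,
    RelationAnnotation,
    RelationParticipant,
    entity_content_key,
    relation_content_key,
)

LOREM = "abcdefghij klmnopqrst uvwxyzabcd efghijklmn opqrstuvwx yzabcdefgh " * 6


def doc(doc_id: str = "d1", text: str = LOREM) -> AnnotatedDocument:
    return AnnotatedDocument(doc_id=doc_id, text=text)


def ent(
    ann_id: str,
    spans,
    etype: str = "T",
    document: AnnotatedDocument | None = None,
    annotator: str = "a",
    round: int = 1,
    origin: Origin = Origin.MANUAL,
) -> EntityAnnotation:
    d = document or doc()
    if isinstance(spans[0], int):
        spans = [spans]
    frags = tuple(Fragment(s, e) for s, e in spans)
    return EntityAnnotation(
        ann_id=ann_id,
        doc_id=d.doc_id,
        etype=etype,
        fragments=frags,
        mention_text=" ".join(d.text[f.start:f.end] for f in frags),
        origin=origin,
        annotator=annotator,
        round=round,
    )


def mrel(ann_id, rtype, refs, doc_id="d1", annotator="a", round=1,
         roles=("Arg1", "Arg2"), origin=Origin.MANUAL):
    return RelationAnnotation(
        ann_id=ann_id,
        doc_id=doc_id,
        rtype=rtype,
        granularity=Granularity.MENTION,
        participants=tuple(
            RelationParticipant(role=role, entity_ref=ref)
            for role, ref in zip(roles, refs)
        ),
        origin=origin,
        annotator=annotator,
        round=round,
    )


def drel(ann_id, rtype, pairs, doc_id="d1", annotator="a", round=1,
         roles=("Arg1", "Arg2")):
    return RelationAnnotation(
        ann_id=ann_id,
        doc_id=doc_id,
        rtype=rtype,
        granularity=Granularity.DOCUMENT,
        participants=tuple(
            RelationParticipant(role=role, name=name, etype=etype)
            for role, (name, etype) in zip(roles, pairs)
        ),
        annotator=annotator,
        round=round,
    )


def aset(annotator, round=1, entities=(), relations=()):
    return AnnotationSet(
        annotator=annotator,
        round=round,
        entities=list(entities),
        relations=list(relations),
    )


def brute_force_max_matching(A, B, min_overlap: int) -> int:
    """Exhaustive maximum one-to-one matched-pair count over candidate
    pairs with span overlap ≥ min_overlap.  Independent of the package's
    matching algorithm: plain recursion over all assignments."""
    from annokit.agreement import span_overlap

    candidates = [
        (i, j)
        for i, a in enumerate(A)
        for j, b in enumerate(B)
        if span_overlap(a, b) >= min_overlap
    ]

    def best(pairs, used_a, used_b):
        if not pairs:
            return 0
        (i, j), rest = pairs[0], pairs[1:]
        skip = best(rest, used_a, used_b)
        if i in used_a or j in used_b:
            return skip
        take = 1 + best(rest, used_a | {i}, used_b | {j})
        return max(take, skip)

    return best(candidates, frozenset(), frozenset())


def random_entity_sets(rng: Random, max_per_side=6, text_len=40, types=("X", "Y")):
    """A pair of random single-document entity lists for matching tests."""
    d = AnnotatedDocument(doc_id="d1", text="z" * text_len)

    def side(prefix):
        out = []
        for i in range(rng.randint(0, max_per_side)):
            start = rng.randrange(text_len - 2)
            end = rng.randint(start + 1, min(text_len, start + rng.randint(1, 12)))
            out.append(
                ent(f"{prefix}{i}", (start, end), rng.choice(types), document=d)
            )
        return out

    return side("A"), side("B")


def entity_keys(entities):
    return sorted(entity_content_key(e) for e in entities)


def relation_keys(relations, entities):
    idx = {e.ann_id: e for e in entities}
    return sorted(repr(relation_content_key(r, idx)) for r in relations)
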