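"""Domain model for collaborative corpus annotation projects.

The model mirrors the life cycle of a multi-annotator, multi-round
annotation effort: a :class:`Project` holds immutable documents, an entity
and relation type schema, a roster of annotators and a sequence of rounds;
each (annotator, round) pair owns one :class:`AnnotationSet`.  Entity
annotations are typed, possibly discontinuous character-span mentions;
relation annotations link participants either at the mention level
(anchored to entity offsets) or at the document level (anchored to
(name, type) pairs, unique per document).

All offsets count Unicode code points, are 0-based and half-open — the
BRAT standoff convention.
"""

from __future__ import annotations

import copy
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "Origin",
    "RoundStatus",
    "Granularity",
    "SchemaError",
    "ValidationError",
    "Fragment",
    "AnnotatedDocument",
    "EntityAnnotation",
    "RelationParticipant",
    "RelationAnnotation",
    "AnnotationSet",
    "RelationType",
    "Project",
    "mention_text_for",
    "entity_content_key",
    "relation_content_key",
    "create_round",
    "copy_annotations",
    "duplicate_round",
    "finalize_round",
]


class Origin(str, Enum):
    """Provenance of an annotation mark."""

    MANUAL = "manual"
    RECOMMENDATION = "recommendation"
    IMPORTED = "imported"


class RoundStatus(str, Enum):
    OPEN = "open"
    FINALIZED = "finalized"


class Granularity(str, Enum):
    """Anchoring level for relation annotations."""

    MENTION = "mention"
    DOCUMENT = "document"


class SchemaError(ValueError):
    """An annotation references a type label absent from the project schema."""


class ValidationError(ValueError):
    """An annotation violates a structural invariant (offsets, text, refs)."""


@dataclass(frozen=True, order=True)
class Fragment:
    """Half-open character interval [start, end) over a document's text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(f"invalid fragment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Fragment") -> int:
        """Number of characters shared with *other* (0 when disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AnnotatedDocument:
    """Plain Unicode text plus identity; the offset reference frame."""

    doc_id: str
    text: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.text)


def mention_text_for(text: str, fragments: Sequence[Fragment]) -> str:
    """Concatenate document substrings at *fragments*, space-joined."""
    return " ".join(text[f.start:f.end] for f in fragments)


def _check_fragments(fragments: Sequence[Fragment]) -> tuple[Fragment, ...]:
    frags = tuple(fragments)
    if not frags:
        raise ValidationError("annotation needs at least one fragment")
    for prev, nxt in zip(frags, frags[1:]):
        if nxt.start < prev.end:
            raise ValidationError(
                f"fragments must be sorted and disjoint: {prev} then {nxt}"
            )
    return frags


@dataclass
class EntityAnnotation:
    """A typed mention: one or more disjoint spans of one document.

    ``mention_text`` is a snapshot of the document substring(s) at the
    fragments; distinct annotations of one annotator may overlap each
    other (partial-word tagging and overlapping marks are permitted).
    """

    ann_id: str
    doc_id: str
    etype: str
    fragments: tuple[Fragment, ...]
    mention_text: str
    origin: Origin = Origin.MANUAL
    annotator: str = ""
    round: int = 1

    def __post_init__(self) -> None:
        self.fragments = _check_fragments(self.fragments)
        if isinstance(self.origin, str):
            self.origin = Origin(self.origin)

    @classmethod
    def from_document(
        cls,
        ann_id: str,
        doc: AnnotatedDocument,
        etype: str,
        fragments: Sequence[Fragment],
        **kw,
    ) -> "EntityAnnotation":
        frags = _check_fragments(fragments)
        if frags[-1].end > len(doc.text):
            raise ValidationError(
                f"fragment {frags[-1]} exceeds document {doc.doc_id!r} "
                f"length {len(doc.text)}"
            )
        return cls(
            ann_id=ann_id,
            doc_id=doc.doc_id,
            etype=etype,
            fragments=frags,
            mention_text=mention_text_for(doc.text, frags),
            **kw,
        )

    @property
    def start(self) -> int:
        return self.fragments[0].start

    @property
    def end(self) -> int:
        return self.fragments[-1].end

    def total_length(self) -> int:
        return sum(len(f) for f in self.fragments)

    def span_signature(self) -> tuple[tuple[int, int], ...]:
        return tuple((f.start, f.end) for f in self.fragments)

    def validate_against(self, doc: AnnotatedDocument) -> None:
        if self.doc_id != doc.doc_id:
            raise ValidationError(
                f"{self.ann_id}: document mismatch {self.doc_id!r} != {doc.doc_id!r}"
            )
        if self.end > len(doc.text):
            raise ValidationError(
                f"{self.ann_id}: offset {self.end} beyond document length {len(doc.text)}"
            )
        expect = mention_text_for(doc.text, self.fragments)
        if self.mention_text != expect:
            raise ValidationError(
                f"{self.ann_id}: mention text {self.mention_text!r} does not match "
                f"document substring {expect!r}"
            )


def normalize_name(name: str) -> str:
    """NFC-normalize and trim an entity surface name for document-level
    relation comparison."""
    return unicodedata.normalize("NFC", name).strip()


@dataclass(frozen=True)
class RelationParticipant:
    """One participant of a relation.

    Exactly one anchor form is populated: ``entity_ref`` (mention level,
    the ann_id of an entity in the same set) or the (``name``, ``etype``)
    pair (document level, no offsets).
    """

    role: str
    entity_ref: Optional[str] = None
    name: Optional[str] = None
    etype: Optional[str] = None

    def __post_init__(self) -> None:
        mention = self.entity_ref is not None
        document = self.name is not None and self.etype is not None
        if mention == document:
            raise ValidationError(
                "participant must carry exactly one anchor: entity_ref "
                "or (name, etype)"
            )

    @property
    def is_mention_level(self) -> bool:
        return self.entity_ref is not None

    def name_key(self, case_sensitive: bool = True) -> tuple[str, str]:
        """Canonical (name, etype) comparison key (document level)."""
        name = normalize_name(self.name or "")
        if not case_sensitive:
            name = name.casefold()
        return (name, self.etype or "")


@dataclass
class RelationAnnotation:
    """A typed relation among ≥2 participants.

    Document-level relations are unique per (participants, type) tuple
    within one (annotator, round, document); mention-level relations may
    repeat, being distinguished by their offset-anchored participants.
    """

    ann_id: str
    doc_id: str
    rtype: str
    granularity: Granularity
    participants: tuple[RelationParticipant, ...]
    origin: Origin = Origin.MANUAL
    annotator: str = ""
    round: int = 1

    def __post_init__(self) -> None:
        self.participants = tuple(self.participants)
        if len(self.participants) < 2:
            raise ValidationError(f"{self.ann_id}: relation needs ≥2 participants")
        if isinstance(self.granularity, str):
            self.granularity = Granularity(self.granularity)
        if isinstance(self.origin, str):
            self.origin = Origin(self.origin)
        want_mention = self.granularity is Granularity.MENTION
        for p in self.participants:
            if p.is_mention_level != want_mention:
                raise ValidationError(
                    f"{self.ann_id}: participant anchor form does not match "
                    f"granularity {self.granularity.value}"
                )

    def document_key(self, case_sensitive: bool = True) -> tuple:
        """Uniqueness key for a document-level relation."""
        parts = tuple(sorted(p.name_key(case_sensitive) for p in self.participants))
        return (self.doc_id, parts, self.rtype)


@dataclass
class AnnotationSet:
    """All annotations of one annotator in one round."""

    annotator: str
    round: int
    entities: list[EntityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def entity_by_id(self, ann_id: str) -> EntityAnnotation:
        for e in self.entities:
            if e.ann_id == ann_id:
                return e
        raise KeyError(ann_id)

    def entities_in(self, doc_id: str) -> list[EntityAnnotation]:
        return [e for e in self.entities if e.doc_id == doc_id]

    def relations_in(self, doc_id: str) -> list[RelationAnnotation]:
        return [r for r in self.relations if r.doc_id == doc_id]

    def next_ids(self) -> tuple[int, int]:
        """Next free numeric suffixes for entity ('E') and relation ('R') ids."""

        def peak(anns: Iterable, prefixes: tuple[str, ...]) -> int:
            best = 0
            for a in anns:
                for p in prefixes:
                    if a.ann_id.startswith(p) and a.ann_id[len(p):].isdigit():
                        best = max(best, int(a.ann_id[len(p):]))
            return best

        return peak(self.entities, ("E", "T")) + 1, peak(self.relations, ("R",)) + 1

    def validate(self, project: Optional["Project"] = None) -> None:
        """Check internal consistency, and schema conformance when a project
        is supplied: all members share (annotator, round), entity refs
        resolve, document-level relations are unique per document."""
        eids = {}
        for e in self.entities:
            if e.annotator != self.annotator or e.round != self.round:
                raise ValidationError(
                    f"{e.ann_id}: provenance ({e.annotator}, {e.round}) does not "
                    f"match set ({self.annotator}, {self.round})"
                )
            if e.ann_id in eids:
                raise ValidationError(f"duplicate entity id {e.ann_id}")
            eids[e.ann_id] = e
        doc_keys: set[tuple] = set()
        for r in self.relations:
            if r.annotator != self.annotator or r.round != self.round:
                raise ValidationError(
                    f"{r.ann_id}: provenance does not match set "
                    f"({self.annotator}, {self.round})"
                )
            if r.granularity is Granularity.MENTION:
                for p in r.participants:
                    ref = eids.get(p.entity_ref or "")
                    if ref is None:
                        raise ValidationError(
                            f"{r.ann_id}: dangling entity reference {p.entity_ref!r}"
                        )
                    if ref.doc_id != r.doc_id:
                        raise ValidationError(
                            f"{r.ann_id}: participant {p.entity_ref} lives in "
                            f"document {ref.doc_id!r}, relation in {r.doc_id!r}"
                        )
            else:
                key = r.document_key()
                if key in doc_keys:
                    raise ValidationError(
                        f"{r.ann_id}: duplicate document-level relation "
                        f"(participants+type occur more than once in {r.doc_id!r})"
                    )
                doc_keys.add(key)
        if project is not None:
            etypes = project.entity_type_labels()
            rtypes = project.relation_type_labels()
            for e in self.entities:
                if e.etype not in etypes:
                    raise SchemaError(f"{e.ann_id}: unknown entity type {e.etype!r}")
                doc = project.documents.get(e.doc_id)
                if doc is None:
                    raise ValidationError(f"{e.ann_id}: unknown document {e.doc_id!r}")
                e.validate_against(doc)
            for r in self.relations:
                if r.rtype not in rtypes:
                    raise SchemaError(f"{r.ann_id}: unknown relation type {r.rtype!r}")
                if r.doc_id not in project.documents:
                    raise ValidationError(f"{r.ann_id}: unknown document {r.doc_id!r}")


def entity_content_key(e: EntityAnnotation) -> tuple:
    """Identity-free content signature, for round-trip comparisons."""
    return (e.doc_id, e.span_signature(), e.etype, e.mention_text)


def relation_content_key(
    r: RelationAnnotation, entity_index: Mapping[str, EntityAnnotation]
) -> tuple:
    """Identity-free relation signature; mention-level participants are
    replaced by their entity content keys."""
    parts = []
    for p in r.participants:
        if p.is_mention_level:
            parts.append((p.role, entity_content_key(entity_index[p.entity_ref])))
        else:
            parts.append((p.role, p.name_key()))
    return (r.doc_id, r.rtype, r.granularity.value, tuple(sorted(parts, key=repr)))


@dataclass(frozen=True)
class RelationType:
    label: str
    arity: int = 2
    directed: bool = True


@dataclass
class Project:
    name: str
    documents: dict[str, AnnotatedDocument] = field(default_factory=dict)
    entity_types: list[tuple[str, str]] = field(default_factory=list)
    relation_types: list[RelationType] = field(default_factory=list)
    annotators: list[str] = field(default_factory=list)
    rounds: dict[int, RoundStatus] = field(default_factory=dict)
    round_meta: dict[int, dict] = field(default_factory=dict)
    sets: dict[tuple[str, int], AnnotationSet] = field(default_factory=dict)
    relation_granularity: Granularity = Granularity.MENTION

    def entity_type_labels(self) -> set[str]:
        return {label for label, _color in self.entity_types}

    def relation_type_labels(self) -> set[str]:
        return {rt.label for rt in self.relation_types}

    def is_directed(self, rtype: str) -> bool:
        for rt in self.relation_types:
            if rt.label == rtype:
                return rt.directed
        return True

    def get_set(self, annotator: str, round: int) -> AnnotationSet:
        try:
            return self.sets[(annotator, round)]
        except KeyError:
            raise KeyError(
                f"no annotation set for annotator {annotator!r} in round {round}"
            ) from None

    def sets_in_round(self, round: int) -> list[AnnotationSet]:
        return [
            self.sets[(a, round)] for a in self.annotators if (a, round) in self.sets
        ]

    def has_relations(self) -> bool:
        return any(s.relations for s in self.sets.values())

    def set_granularity(self, granularity: Granularity) -> None:
        """Switch the relation anchoring level.

        Permitted only while no relation annotations exist anywhere in the
        project — the two anchor forms are not convertible in place.
        """
        granularity = Granularity(granularity)
        if granularity is self.relation_granularity:
            return
        if self.has_relations():
            raise ValidationError(
                "cannot switch relation granularity while relation "
                "annotations exist; delete them first"
            )
        self.relation_granularity = granularity

    def add_document(self, doc: AnnotatedDocument) -> None:
        if doc.doc_id in self.documents:
            raise ValidationError(f"duplicate document id {doc.doc_id!r}")
        self.documents[doc.doc_id] = doc


# ---------------------------------------------------------------------------
# Round life cycle
# ---------------------------------------------------------------------------


def create_round(
    project: Project,
    seed_sets: Optional[Mapping[str, AnnotationSet]] = None,
) -> int:
    """Open a new annotation round: number = max existing + 1 (or 1), one
    empty (or seeded) set per registered annotator.

    Seed sets are validated against the project schema before anything is
    mutated; an unknown annotator or type label raises and leaves the
    project untouched.
    """
    if not project.annotators:
        raise ValidationError("project has no annotators")
    new_round = max(project.rounds, default=0) + 1
    staged: dict[tuple[str, int], AnnotationSet] = {}
    seed_sets = dict(seed_sets or {})
    for annotator in seed_sets:
        if annotator not in project.annotators:
            raise SchemaError(f"unknown annotator {annotator!r} in seed sets")
    for annotator in project.annotators:
        seed = seed_sets.get(annotator)
        if seed is None:
            staged[(annotator, new_round)] = AnnotationSet(annotator, new_round)
        else:
            fresh = _rebind_set(seed, annotator, new_round)
            fresh.validate(project)
            staged[(annotator, new_round)] = fresh
    project.rounds[new_round] = RoundStatus.OPEN
    project.round_meta.setdefault(new_round, {})
    project.sets.update(staged)
    return new_round


def _rebind_set(source: AnnotationSet, annotator: str, round: int) -> AnnotationSet:
    """Deep copy *source* onto (annotator, round) with fresh ann_ids and
    consistently remapped mention-level entity references."""
    entities: list[EntityAnnotation] = []
    id_map: dict[str, str] = {}
    for i, e in enumerate(
        sorted(source.entities, key=lambda e: (e.doc_id, e.span_signature(), e.ann_id)),
        start=1,
    ):
        new = copy.deepcopy(e)
        new.ann_id = f"E{i}"
        new.annotator = annotator
        new.round = round
        id_map[e.ann_id] = new.ann_id
        entities.append(new)
    relations: list[RelationAnnotation] = []
    for j, r in enumerate(
        sorted(source.relations, key=lambda r: (r.doc_id, r.ann_id)), start=1
    ):
        new_parts = []
        for p in r.participants:
            if p.is_mention_level:
                if p.entity_ref not in id_map:
                    raise ValidationError(
                        f"{r.ann_id}: entity reference {p.entity_ref!r} not in set"
                    )
                new_parts.append(
                    RelationParticipant(role=p.role, entity_ref=id_map[p.entity_ref])
                )
            else:
                new_parts.append(p)
        relations.append(
            RelationAnnotation(
                ann_id=f"R{j}",
                doc_id=r.doc_id,
                rtype=r.rtype,
                granularity=r.granularity,
                participants=tuple(new_parts),
                origin=r.origin,
                annotator=annotator,
                round=round,
            )
        )
    return AnnotationSet(annotator, round, entities, relations)


def copy_annotations(
    project: Project,
    round: int,
    from_annotator: str,
    to_annotator: str,
    overwrite: bool = False,
) -> AnnotationSet:
    """Hand one annotator's work to another for independent revision.

    The target set is replaced by a deep copy with rewritten provenance and
    fresh ids (relation references remapped); later edits to either set do
    not affect the other.  Copying onto a non-empty target requires
    ``overwrite=True``.
    """
    source = project.get_set(from_annotator, round)
    if to_annotator not in project.annotators:
        raise SchemaError(f"unknown annotator {to_annotator!r}")
    target = project.sets.get((to_annotator, round))
    if target is not None and (target.entities or target.relations) and not overwrite:
        raise ValidationError(
            f"target set ({to_annotator!r}, round {round}) is not empty; "
            "pass overwrite=True to replace it"
        )
    fresh = _rebind_set(source, to_annotator, round)
    project.sets[(to_annotator, round)] = fresh
    return fresh


def duplicate_round(project: Project, round: int) -> int:
    """Create a checkpoint: a new round holding deep copies of every
    annotator's set, for rollback when a guideline change proves
    detrimental.  The original round is untouched."""
    if round not in project.rounds:
        raise ValidationError(f"unknown round {round}")
    new_round = max(project.rounds, default=0) + 1
    project.rounds[new_round] = RoundStatus.OPEN
    project.round_meta[new_round] = {"checkpoint_of": round}
    for annotator in project.annotators:
        src = project.sets.get((annotator, round))
        if src is not None:
            project.sets[(annotator, new_round)] = _rebind_set(
                src, annotator, new_round
            )
    return new_round


def finalize_round(project: Project, round: int) -> int:
    """Close a round: every remaining machine recommendation is accepted as
    a valid (manual) annotation.  Returns the number of origins flipped."""
    status = project.rounds.get(round)
    if status is None:
        raise ValidationError(f"unknown round {round}")
    if status is RoundStatus.FINALIZED:
        raise ValidationError(f"round {round} is already finalized")
    flipped = 0
    for annotator in project.annotators:
        s = project.sets.get((annotator, round))
        if s is None:
            continue
        for ann in [*s.entities, *s.relations]:
            if ann.origin is Origin.RECOMMENDATION:
                ann.origin = Origin.MANUAL
                flipped += 1
    project.rounds[round] = RoundStatus.FINALIZED
    return flipped
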