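"""BRAT standoff format (.txt + .ann).

Entity lines: ``T<id>\\t<Type> <start> <end>[;<start> <end>...]\\t<text>``
Relation lines: ``R<id>\\t<Type> <Role1>:T<i> <Role2>:T<j>``

Attribute (A), normalization (N), event (E), modification (M) and note
(#) lines are outside this tool's data model and are reported as skipped.
Discontinuous spans become multi-fragment entities whose mention text is
the space-joined concatenation of the fragments.
"""

from __future__ import annotations

from typing import Optional, Sequence

from ..model import (
    AnnotatedDocument,
    EntityAnnotation,
    Fragment,
    Granularity,
    Origin,
    RelationAnnotation,
    RelationParticipant,
    ValidationError,
    mention_text_for,
)
from .report import ImportReport

__all__ = ["BratParseError", "read_brat", "write_brat", "parse_standoff_lines"]


class BratParseError(ValidationError):
    """A standoff line carries offsets or text inconsistent with the
    document; the message names the offending line."""


def _parse_entity_line(
    line: str, lineno: int, doc: AnnotatedDocument, on_mismatch: str
) -> EntityAnnotation:
    parts = line.split("\t")
    if len(parts) < 2:
        raise ValueError("entity line needs id, type+offsets and text")
    ann_id = parts[0]
    head = parts[1].split(" ", 1)
    if len(head) != 2:
        raise ValueError("missing offsets")
    etype, span_str = head
    fragments = []
    for chunk in span_str.split(";"):
        nums = chunk.split()
        if len(nums) != 2:
            raise ValueError(f"bad span {chunk!r}")
        fragments.append(Fragment(int(nums[0]), int(nums[1])))
    fragments.sort()
    if fragments[-1].end > len(doc.text):
        raise BratParseError(
            f"line {lineno}: offset {fragments[-1].end} beyond document "
            f"length {len(doc.text)}"
        )
    computed = mention_text_for(doc.text, fragments)
    given = parts[2] if len(parts) > 2 else computed
    if given != computed:
        if on_mismatch == "repair":
            given = computed
        else:
            raise BratParseError(
                f"line {lineno}: mention text {given!r} does not match "
                f"document substring {computed!r}"
            )
    return EntityAnnotation(
        ann_id=ann_id,
        doc_id=doc.doc_id,
        etype=etype,
        fragments=tuple(fragments),
        mention_text=given,
        origin=Origin.IMPORTED,
    )


def _parse_relation_line(line: str, lineno: int, known_ids: set[str]) -> tuple:
    parts = line.split("\t")
    if len(parts) < 2:
        raise ValueError("relation line needs id and type+arguments")
    ann_id = parts[0]
    tokens = parts[1].split()
    if len(tokens) < 3:
        raise ValueError("relation needs a type and ≥2 arguments")
    rtype = tokens[0]
    participants = []
    for tok in tokens[1:]:
        role, _, ref = tok.partition(":")
        if not ref:
            raise ValueError(f"bad argument {tok!r}")
        if ref not in known_ids:
            raise BratParseError(
                f"line {lineno}: relation {ann_id} references unknown entity {ref!r}"
            )
        participants.append(RelationParticipant(role=role, entity_ref=ref))
    return ann_id, rtype, tuple(participants)


def parse_standoff_lines(
    content: str,
    doc: AnnotatedDocument,
    report: ImportReport,
    entities: dict[str, EntityAnnotation],
    relations: list[RelationAnnotation],
    on_mismatch: str = "error",
    source: str = "",
) -> None:
    """Shared line walker for BRAT and BioNLP standoff files."""
    pending_relations: list[tuple[int, str]] = []
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        locator = f"{source}:{lineno}" if source else str(lineno)
        tag = line[0]
        if tag == "T":
            try:
                ann = _parse_entity_line(line, lineno, doc, on_mismatch)
            except BratParseError:
                raise
            except (ValueError, ValidationError) as exc:
                report.skip(locator, f"malformed line: {exc}")
                continue
            if ann.ann_id in entities:
                raise BratParseError(
                    f"line {lineno}: duplicate entity id {ann.ann_id!r}"
                )
            entities[ann.ann_id] = ann
        elif tag == "R":
            pending_relations.append((lineno, line))
        elif tag in "ANEM#*":
            report.skip(locator, "unsupported line type")
        else:
            report.skip(locator, "malformed line: unknown line tag")
    for lineno, line in pending_relations:
        locator = f"{source}:{lineno}" if source else str(lineno)
        try:
            ann_id, rtype, participants = _parse_relation_line(
                line, lineno, set(entities)
            )
        except BratParseError:
            raise
        except ValueError as exc:
            report.skip(locator, f"malformed line: {exc}")
            continue
        relations.append(
            RelationAnnotation(
                ann_id=ann_id,
                doc_id=doc.doc_id,
                rtype=rtype,
                granularity=Granularity.MENTION,
                participants=participants,
                origin=Origin.IMPORTED,
            )
        )


def read_brat(
    text_content: str,
    ann_content: str,
    doc_id: str,
    on_mismatch: str = "error",
) -> tuple[AnnotatedDocument, list[EntityAnnotation], list[RelationAnnotation], ImportReport]:
    """Parse one BRAT document pair.

    ``on_mismatch`` chooses between raising on a mention/offset text
    disagreement (default) and repairing the mention text from the
    offsets ("repair").
    """
    doc = AnnotatedDocument(doc_id=doc_id, text=text_content)
    report = ImportReport(n_documents=1)
    entities: dict[str, EntityAnnotation] = {}
    relations: list[RelationAnnotation] = []
    parse_standoff_lines(
        ann_content, doc, report, entities, relations, on_mismatch=on_mismatch
    )
    out_entities = sorted(entities.values(), key=lambda e: (e.start, e.ann_id))
    report.n_entities = len(out_entities)
    report.n_relations = len(relations)
    return doc, out_entities, relations, report


def write_brat(
    doc: AnnotatedDocument,
    entities: Sequence[EntityAnnotation],
    relations: Sequence[RelationAnnotation] = (),
) -> tuple[str, str]:
    """Serialize one document to a (.txt, .ann) pair.

    Ids are renumbered deterministically in (start, span, id) order;
    relation references are remapped accordingly.
    """
    id_map: dict[str, str] = {}
    lines: list[str] = []
    for i, e in enumerate(
        sorted(entities, key=lambda e: (e.span_signature(), e.etype, e.ann_id)),
        start=1,
    ):
        tid = f"T{i}"
        id_map[e.ann_id] = tid
        span_str = ";".join(f"{f.start} {f.end}" for f in e.fragments)
        lines.append(f"{tid}\t{e.etype} {span_str}\t{e.mention_text}")
    for j, r in enumerate(sorted(relations, key=lambda r: r.ann_id), start=1):
        if r.granularity is not Granularity.MENTION:
            raise ValidationError(
                f"{r.ann_id}: BRAT standoff cannot express document-level relations"
            )
        args = " ".join(f"{p.role}:{id_map[p.entity_ref]}" for p in r.participants)
        lines.append(f"R{j}\t{r.rtype} {args}")
    ann = "\n".join(lines) + ("\n" if lines else "")
    return doc.text, ann
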