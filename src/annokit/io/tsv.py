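"""TSV dialects.

Import dialects (auto-detected by column count, overridable):

* document rows — ``doc_id<TAB>title<TAB>body`` (3 columns); the document
  text becomes ``title + "\\n" + body``;
* entity rows — ``doc_id<TAB>type<TAB>start<TAB>end<TAB>text``
  (5 columns), the BioCreative-style entity table.

The standoff export dialect is a single self-describing table carrying
entities and relations alike::

    doc_id  ann_id  kind(E|R)  type  offsets("s:e[;s:e]" or "-")
    text_or_participants  annotator  round  origin

Participants serialize as ``role:ann_id`` (mention level) or
``role:name|etype`` (document level), comma-separated.
"""

from __future__ import annotations

import csv
import io as _io
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
)
from .report import ImportReport

__all__ = [
    "read_tsv",
    "read_tsv_standoff",
    "STANDOFF_HEADER",
    "entity_standoff_row",
    "relation_standoff_row",
]

STANDOFF_HEADER = [
    "doc_id",
    "ann_id",
    "kind",
    "type",
    "offsets",
    "text_or_participants",
    "annotator",
    "round",
    "origin",
]


def _rows(content: str) -> list[tuple[int, list[str]]]:
    reader = csv.reader(_io.StringIO(content), delimiter="\t", quoting=csv.QUOTE_NONE)
    return [(i, row) for i, row in enumerate(reader, start=1) if row and any(row)]


def read_tsv(
    content: str,
    dialect: Optional[str] = None,
    documents: Optional[dict[str, AnnotatedDocument]] = None,
) -> tuple[dict[str, AnnotatedDocument], list[EntityAnnotation], ImportReport]:
    """Read a document-table or entity-table TSV.

    ``dialect`` is "documents", "entities" or None (auto-detect from the
    first row's column count: 3 → documents, 5 → entities).  When a
    *documents* map is provided, entity offsets and text are validated
    against it.  Ragged rows are skipped with a reason.
    """
    rows = _rows(content)
    report = ImportReport()
    docs: dict[str, AnnotatedDocument] = {}
    entities: list[EntityAnnotation] = []
    if not rows:
        return docs, entities, report
    if dialect is None:
        dialect = "documents" if len(rows[0][1]) == 3 else "entities"
    if dialect not in ("documents", "entities"):
        raise ValueError(f"unknown TSV dialect {dialect!r}")
    want = 3 if dialect == "documents" else 5
    for lineno, row in rows:
        if len(row) != want:
            report.skip(str(lineno), f"expected {want} columns, got {len(row)}")
            continue
        if dialect == "documents":
            doc_id, title, body = row
            if doc_id in docs:
                report.skip(str(lineno), f"duplicate document id {doc_id!r}")
                continue
            docs[doc_id] = AnnotatedDocument(doc_id=doc_id, text=f"{title}\n{body}")
            report.n_documents += 1
        else:
            doc_id, etype, start_s, end_s, text = row
            try:
                frag = Fragment(int(start_s), int(end_s))
            except (ValueError, ValidationError) as exc:
                report.skip(str(lineno), f"bad offsets: {exc}")
                continue
            if documents is not None:
                doc = documents.get(doc_id)
                if doc is None:
                    raise ValidationError(
                        f"line {lineno}: unknown document {doc_id!r}"
                    )
                if frag.end > len(doc.text):
                    raise ValidationError(
                        f"line {lineno}: offset {frag.end} beyond document "
                        f"length {len(doc.text)}"
                    )
                if doc.text[frag.start:frag.end] != text:
                    raise ValidationError(
                        f"line {lineno}: text {text!r} does not match document "
                        f"substring {doc.text[frag.start:frag.end]!r}"
                    )
            entities.append(
                EntityAnnotation(
                    ann_id=f"E{len(entities) + 1}",
                    doc_id=doc_id,
                    etype=etype,
                    fragments=(frag,),
                    mention_text=text,
                    origin=Origin.IMPORTED,
                )
            )
            report.n_entities += 1
    return docs, entities, report


def entity_standoff_row(e: EntityAnnotation) -> list[str]:
    offsets = ";".join(f"{f.start}:{f.end}" for f in e.fragments)
    return [
        e.doc_id,
        e.ann_id,
        "E",
        e.etype,
        offsets,
        e.mention_text,
        e.annotator,
        str(e.round),
        e.origin.value,
    ]


def relation_standoff_row(r: RelationAnnotation) -> list[str]:
    if r.granularity is Granularity.MENTION:
        parts = ",".join(f"{p.role}:{p.entity_ref}" for p in r.participants)
    else:
        parts = ",".join(f"{p.role}:{p.name}|{p.etype}" for p in r.participants)
    return [
        r.doc_id,
        r.ann_id,
        "R",
        r.rtype,
        "-",
        parts,
        r.annotator,
        str(r.round),
        r.origin.value,
    ]


def read_tsv_standoff(
    content: str,
) -> tuple[list[EntityAnnotation], list[RelationAnnotation], ImportReport]:
    """Parse the standoff export dialect back into annotations."""
    report = ImportReport()
    entities: list[EntityAnnotation] = []
    relations: list[RelationAnnotation] = []
    rows = _rows(content)
    for lineno, row in rows:
        if row == STANDOFF_HEADER:
            continue
        if len(row) != len(STANDOFF_HEADER):
            report.skip(str(lineno), f"expected {len(STANDOFF_HEADER)} columns")
            continue
        doc_id, ann_id, kind, atype, offsets, payload, annotator, round_s, origin = row
        try:
            rnd = int(round_s)
        except ValueError:
            report.skip(str(lineno), f"bad round {round_s!r}")
            continue
        if kind == "E":
            frags = tuple(
                Fragment(int(s), int(e))
                for s, e in (chunk.split(":") for chunk in offsets.split(";"))
            )
            entities.append(
                EntityAnnotation(
                    ann_id=ann_id,
                    doc_id=doc_id,
                    etype=atype,
                    fragments=frags,
                    mention_text=payload,
                    origin=Origin(origin),
                    annotator=annotator,
                    round=rnd,
                )
            )
            report.n_entities += 1
        elif kind == "R":
            participants = []
            mention_level = None
            for part in payload.split(","):
                role, _, anchor = part.partition(":")
                if "|" in anchor:
                    name, _, etype = anchor.rpartition("|")
                    participants.append(
                        RelationParticipant(role=role, name=name, etype=etype)
                    )
                    mention_level = False
                else:
                    participants.append(
                        RelationParticipant(role=role, entity_ref=anchor)
                    )
                    mention_level = True
            relations.append(
                RelationAnnotation(
                    ann_id=ann_id,
                    doc_id=doc_id,
                    rtype=atype,
                    granularity=(
                        Granularity.MENTION if mention_level else Granularity.DOCUMENT
                    ),
                    participants=tuple(participants),
                    origin=Origin(origin),
                    annotator=annotator,
                    round=rnd,
                )
            )
            report.n_relations += 1
        else:
            report.skip(str(lineno), f"unknown kind {kind!r}")
    return entities, relations, report
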