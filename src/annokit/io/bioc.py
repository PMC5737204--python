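"""BioC inline XML.

A collection holds documents; each document holds passages carrying an
``offset`` and a text.  The document text is reconstructed by placing
every passage at its offset (gaps become spaces), and annotation
locations (offset + length) are interpreted as absolute document
offsets — the common BioC convention.  Relation elements reference
annotations by ``refid``; document-level relation participants (which
have no offsets) travel as ``participant:<role>`` infons encoding
``name|type``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
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

__all__ = ["read_bioc", "write_bioc"]


def _infons(elem: ET.Element) -> dict[str, str]:
    return {
        i.get("key", ""): (i.text or "")
        for i in elem.findall("infon")
    }


def read_bioc(
    xml_content: str,
    on_mismatch: str = "error",
    strict_passages: bool = False,
) -> tuple[
    dict[str, AnnotatedDocument],
    list[EntityAnnotation],
    list[RelationAnnotation],
    ImportReport,
]:
    """Parse a BioC collection.

    ``strict_passages`` additionally re-validates every annotation
    against the bounds of the passage that contains its first offset.
    """
    report = ImportReport()
    try:
        root = ET.fromstring(xml_content)
    except ET.ParseError as exc:
        raise ValidationError(f"not well-formed BioC XML: {exc}") from exc
    documents: dict[str, AnnotatedDocument] = {}
    entities: list[EntityAnnotation] = []
    relations: list[RelationAnnotation] = []
    for doc_elem in root.iter("document"):
        doc_id = (doc_elem.findtext("id") or "").strip()
        passages = []
        for p in doc_elem.findall("passage"):
            offset = int((p.findtext("offset") or "0").strip())
            passages.append((offset, p.findtext("text") or "", p))
        passages.sort(key=lambda t: t[0])
        total = max((off + len(txt) for off, txt, _p in passages), default=0)
        buf = [" "] * total
        for off, txt, _p in passages:
            buf[off:off + len(txt)] = list(txt)
        doc = AnnotatedDocument(doc_id=doc_id, text="".join(buf))
        documents[doc_id] = doc
        report.n_documents += 1

        ann_elems: list[tuple[ET.Element, Optional[tuple[int, int]]]] = []
        rel_elems: list[ET.Element] = []
        for off, txt, p in passages:
            for a in p.findall("annotation"):
                ann_elems.append((a, (off, off + len(txt))))
            rel_elems.extend(p.findall("relation"))
        for a in doc_elem.findall("annotation"):
            ann_elems.append((a, None))
        rel_elems.extend(doc_elem.findall("relation"))

        seen_ids: dict[str, EntityAnnotation] = {}
        for a, bounds in ann_elems:
            aid = a.get("id", "")
            infons = _infons(a)
            etype = infons.get("type")
            if not etype:
                report.skip(f"{doc_id}/annotation {aid!r}", "missing infon 'type'")
                continue
            fragments = []
            for loc in a.findall("location"):
                off = int(loc.get("offset", "0"))
                length = int(loc.get("length", "0"))
                fragments.append(Fragment(off, off + length))
            if not fragments:
                report.skip(f"{doc_id}/annotation {aid!r}", "no location")
                continue
            fragments.sort()
            if fragments[-1].end > len(doc.text):
                raise ValidationError(
                    f"{doc_id}/annotation {aid!r}: offset {fragments[-1].end} "
                    f"beyond document length {len(doc.text)}"
                )
            if strict_passages and bounds is not None:
                lo, hi = bounds
                if fragments[0].start < lo or fragments[-1].end > hi:
                    raise ValidationError(
                        f"{doc_id}/annotation {aid!r}: span outside its passage "
                        f"[{lo}, {hi})"
                    )
            computed = mention_text_for(doc.text, fragments)
            given = a.findtext("text")
            mention = computed if given is None else given
            if mention != computed:
                if on_mismatch == "repair":
                    mention = computed
                else:
                    raise ValidationError(
                        f"{doc_id}/annotation {aid!r}: text {mention!r} does not "
                        f"match document substring {computed!r}"
                    )
            ann = EntityAnnotation(
                ann_id=aid,
                doc_id=doc_id,
                etype=etype,
                fragments=tuple(fragments),
                mention_text=mention,
                origin=Origin(infons.get("origin", Origin.IMPORTED.value)),
                annotator=infons.get("annotator", ""),
                round=int(infons.get("round", "1")),
            )
            seen_ids[aid] = ann
            entities.append(ann)

        for r in rel_elems:
            rid = r.get("id", "")
            infons = _infons(r)
            rtype = infons.get("type")
            if not rtype:
                report.skip(f"{doc_id}/relation {rid!r}", "missing infon 'type'")
                continue
            doc_parts = sorted(
                (k, v) for k, v in infons.items() if k.startswith("participant:")
            )
            if doc_parts:
                participants = []
                for key, value in doc_parts:
                    name, _, etype = value.rpartition("|")
                    participants.append(
                        RelationParticipant(
                            role=key.split(":", 1)[1], name=name, etype=etype
                        )
                    )
                granularity = Granularity.DOCUMENT
            else:
                participants = []
                for node in r.findall("node"):
                    refid = node.get("refid", "")
                    if refid not in seen_ids:
                        raise ValidationError(
                            f"{doc_id}/relation {rid!r}: dangling refid {refid!r}"
                        )
                    participants.append(
                        RelationParticipant(
                            role=node.get("role", ""), entity_ref=refid
                        )
                    )
                granularity = Granularity.MENTION
            relations.append(
                RelationAnnotation(
                    ann_id=rid,
                    doc_id=doc_id,
                    rtype=rtype,
                    granularity=granularity,
                    participants=tuple(participants),
                    origin=Origin(infons.get("origin", Origin.IMPORTED.value)),
                    annotator=infons.get("annotator", ""),
                    round=int(infons.get("round", "1")),
                )
            )
    report.n_entities = len(entities)
    report.n_relations = len(relations)
    return documents, entities, relations, report


def _infon(parent: ET.Element, key: str, value: str) -> None:
    e = ET.SubElement(parent, "infon", key=key)
    e.text = value


def write_bioc(
    documents: Sequence[AnnotatedDocument],
    entities: Sequence[EntityAnnotation],
    relations: Sequence[RelationAnnotation] = (),
    source: str = "annokit",
) -> str:
    """Serialize to a BioC collection: one passage per document at offset
    0, with provenance (annotator, round, origin) carried as infons.
    Output is deterministic — identical inputs yield identical bytes."""
    root = ET.Element("collection")
    ET.SubElement(root, "source").text = source
    by_doc_e: dict[str, list[EntityAnnotation]] = {}
    by_doc_r: dict[str, list[RelationAnnotation]] = {}
    for e in entities:
        by_doc_e.setdefault(e.doc_id, []).append(e)
    for r in relations:
        by_doc_r.setdefault(r.doc_id, []).append(r)
    for doc in sorted(documents, key=lambda d: d.doc_id):
        doc_elem = ET.SubElement(root, "document")
        ET.SubElement(doc_elem, "id").text = doc.doc_id
        passage = ET.SubElement(doc_elem, "passage")
        ET.SubElement(passage, "offset").text = "0"
        ET.SubElement(passage, "text").text = doc.text
        for e in sorted(
            by_doc_e.get(doc.doc_id, []),
            key=lambda e: (e.span_signature(), e.etype, e.ann_id),
        ):
            a = ET.SubElement(passage, "annotation", id=e.ann_id)
            _infon(a, "type", e.etype)
            _infon(a, "annotator", e.annotator)
            _infon(a, "round", str(e.round))
            _infon(a, "origin", e.origin.value)
            for f in e.fragments:
                ET.SubElement(
                    a, "location", offset=str(f.start), length=str(len(f))
                )
            ET.SubElement(a, "text").text = e.mention_text
        for r in sorted(by_doc_r.get(doc.doc_id, []), key=lambda r: r.ann_id):
            rel = ET.SubElement(passage, "relation", id=r.ann_id)
            _infon(rel, "type", r.rtype)
            _infon(rel, "annotator", r.annotator)
            _infon(rel, "round", str(r.round))
            _infon(rel, "origin", r.origin.value)
            if r.granularity is Granularity.DOCUMENT:
                for p in r.participants:
                    _infon(rel, f"participant:{p.role}", f"{p.name}|{p.etype}")
            else:
                for p in r.participants:
                    ET.SubElement(rel, "node", refid=p.entity_ref or "", role=p.role)
    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    ) + "\n"
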