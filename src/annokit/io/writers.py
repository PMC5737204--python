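"""Corpus export: one (annotator, round) set to standoff TSV, inline
TSV, JSON or BioC XML.  All writers are deterministic — identical inputs
produce identical bytes (stable (doc_id, start, ann_id) ordering)."""

from __future__ import annotations

import csv
import io as _io
from typing import Iterable

from ..model import AnnotationSet, EntityAnnotation, Project
from .bioc import write_bioc
from .json_io import dumps_project
from .tsv import STANDOFF_HEADER, entity_standoff_row, relation_standoff_row

__all__ = ["write_corpus", "FORMATS"]

FORMATS = ("tsv_standoff", "tsv_inline", "json", "bioc")


def _sorted_entities(s: AnnotationSet) -> list[EntityAnnotation]:
    return sorted(s.entities, key=lambda e: (e.doc_id, e.span_signature(), e.ann_id))


def _tsv_standoff(project: Project, s: AnnotationSet) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
    writer.writerow(STANDOFF_HEADER)
    for e in _sorted_entities(s):
        writer.writerow(entity_standoff_row(e))
    for r in sorted(s.relations, key=lambda r: (r.doc_id, r.ann_id)):
        writer.writerow(relation_standoff_row(r))
    return buf.getvalue()


def _tsv_inline(project: Project, s: AnnotationSet) -> str:
    """Inline dialect: document text with entity marks
    ``[[type|ann_id:mention]]``; nested/overlapping marks are opened in
    (start, −length) order and closed innermost-first."""
    lines = []
    for doc_id in sorted(project.documents):
        doc = project.documents[doc_id]
        anns = sorted(
            s.entities_in(doc_id),
            key=lambda e: (e.start, -e.total_length(), e.ann_id),
        )
        events: list[tuple[int, int, tuple, str]] = []
        for e in anns:
            open_key = (e.start, -e.total_length(), e.ann_id)
            events.append((e.start, 1, open_key, f"[[{e.etype}|{e.ann_id}:"))
            events.append((e.end, 0, (-e.start, e.ann_id), "]]"))
        events.sort(key=lambda ev: (ev[0], ev[1], ev[2]))
        out, cursor = [], 0
        for pos, _kind, _key, mark in events:
            out.append(doc.text[cursor:pos])
            out.append(mark)
            cursor = pos
        out.append(doc.text[cursor:])
        text = "".join(out).replace("\n", "\\n")
        lines.append(f"{doc_id}\t{text}")
    return "\n".join(lines) + "\n"


def write_corpus(
    project: Project,
    round: int,
    annotator_or_consensus: str,
    format: str,
) -> bytes:
    """Serialize the selected set.  ``annotator_or_consensus`` names a
    registered annotator or the "consensus" set stored for the round."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    s = project.get_set(annotator_or_consensus, round)
    if format == "tsv_standoff":
        return _tsv_standoff(project, s).encode("utf-8")
    if format == "tsv_inline":
        return _tsv_inline(project, s).encode("utf-8")
    if format == "json":
        return dumps_project(project, only_sets=[s]).encode("utf-8")
    docs = [project.documents[d] for d in sorted(project.documents)]
    return write_bioc(docs, _sorted_entities(s), sorted(
        s.relations, key=lambda r: (r.doc_id, r.ann_id)
    )).encode("utf-8")
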