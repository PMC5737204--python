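"""BioNLP shared-task standoff representation (.txt + .a1 + .a2).

Same line grammar as BRAT; .a1 carries the given entities, .a2 the
task output (entities and relations).  Event (E) lines carry trigger
semantics outside this data model and are reported as skipped.  Entity
ids must be unique across the two files.
"""

from __future__ import annotations

from ..model import AnnotatedDocument, EntityAnnotation, RelationAnnotation
from .brat import BratParseError, parse_standoff_lines
from .report import ImportReport

__all__ = ["read_bionlp"]


def read_bionlp(
    text_content: str,
    a1_content: str,
    a2_content: str,
    doc_id: str,
    on_mismatch: str = "error",
) -> tuple[AnnotatedDocument, list[EntityAnnotation], list[RelationAnnotation], ImportReport]:
    doc = AnnotatedDocument(doc_id=doc_id, text=text_content)
    report = ImportReport(n_documents=1)
    entities: dict[str, EntityAnnotation] = {}
    relations: list[RelationAnnotation] = []
    parse_standoff_lines(
        a1_content, doc, report, entities, relations,
        on_mismatch=on_mismatch, source="a1",
    )
    try:
        parse_standoff_lines(
            a2_content, doc, report, entities, relations,
            on_mismatch=on_mismatch, source="a2",
        )
    except BratParseError as exc:
        if "duplicate entity id" in str(exc):
            raise BratParseError(f"a1/a2 id collision — {exc}") from None
        raise
    out = sorted(entities.values(), key=lambda e: (e.start, e.ann_id))
    report.n_entities = len(out)
    report.n_relations = len(relations)
    return doc, out, relations, report
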