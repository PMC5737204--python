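"""Dictionary- and history-based annotation recommendations.

A lexicon of surface forms (harvested from prior manual annotations,
loaded from a two-column dictionary, or supplied by an external named
entity recognizer) is projected onto a document: every un-annotated
occurrence of a known form, sitting on word boundaries, becomes a
recommendation.  Recommendations keep ``origin=recommendation`` until
round finalization silently accepts whatever the annotators left in
place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    AnnotatedDocument,
    AnnotationSet,
    EntityAnnotation,
    Fragment,
    Origin,
    Project,
    SchemaError,
    ValidationError,
)

__all__ = [
    "Lexicon",
    "harvest_lexicon",
    "load_dictionary",
    "generate_recommendations",
    "import_predictions",
]


@dataclass
class Lexicon:
    """Surface form → {entity type → frequency} lookup.

    ``source`` records where the entries came from: the annotators' own
    history, a curated dictionary, or an external prediction system.
    """

    entries: dict[str, dict[str, int]] = field(default_factory=dict)
    case_sensitive: bool = True
    source: str = "history"  # history | dictionary | external

    def _norm(self, form: str) -> str:
        return form if self.case_sensitive else form.casefold()

    def add(self, form: str, etype: str, count: int = 1) -> None:
        if not form:
            raise ValueError("empty surface form")
        if count < 1:
            raise ValueError("frequency must be ≥ 1")
        slot = self.entries.setdefault(self._norm(form), {})
        slot[etype] = slot.get(etype, 0) + count

    def best_type(self, form: str) -> Optional[str]:
        """Highest-frequency type for a form; ties broken alphabetically."""
        slot = self.entries.get(self._norm(form))
        if not slot:
            return None
        return min(slot, key=lambda t: (-slot[t], t))

    def forms_by_length(self) -> list[str]:
        return sorted(self.entries, key=lambda f: (-len(f), f))


def harvest_lexicon(sets: Sequence[AnnotationSet], case_sensitive: bool = True) -> Lexicon:
    """Tally every (mention text, type) of *manual* entity annotations;
    pending recommendations and raw imports are excluded so the lexicon
    reflects only what a human asserted."""
    lex = Lexicon(case_sensitive=case_sensitive, source="history")
    for s in sets:
        for e in s.entities:
            if e.origin is Origin.MANUAL and e.mention_text:
                lex.add(e.mention_text, e.etype)
    return lex


def load_dictionary(tsv: str, case_sensitive: bool = True) -> Lexicon:
    """Two-column TSV dictionary: ``surface_form<TAB>type`` per line."""
    lex = Lexicon(case_sensitive=case_sensitive, source="dictionary")
    for line in tsv.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0]:
            continue
        lex.add(parts[0], parts[1])
    return lex


def _occupied(existing: Iterable[EntityAnnotation]) -> list[tuple[int, int]]:
    spans = []
    for e in existing:
        for f in e.fragments:
            spans.append((f.start, f.end))
    return spans


def _word_bounded(text: str, start: int, end: int) -> bool:
    left_ok = start == 0 or not text[start - 1].isalnum()
    right_ok = end == len(text) or not text[end].isalnum()
    return left_ok and right_ok


def generate_recommendations(
    doc: AnnotatedDocument,
    lexicon: Lexicon,
    existing: Sequence[EntityAnnotation] = (),
    annotator: str = "",
    round: int = 1,
    word_boundaries: bool = True,
    id_start: int = 1,
) -> list[EntityAnnotation]:
    """Point out potential misses: left-to-right, longest-match-first scan
    of the document for lexicon forms without an annotation.

    Candidates overlapping an existing annotation or an already emitted
    recommendation are skipped; ``word_boundaries=False`` lifts the
    boundary requirement (for scripts without word spacing).
    """
    for e in existing:
        if e.doc_id != doc.doc_id:
            raise ValidationError(
                f"{e.ann_id}: belongs to {e.doc_id!r}, not {doc.doc_id!r}"
            )
    taken = _occupied(existing)
    forms = lexicon.forms_by_length()
    haystack = doc.text if lexicon.case_sensitive else doc.text.casefold()
    out: list[EntityAnnotation] = []
    n = id_start
    pos = 0
    while pos < len(haystack):
        hit = None
        for form in forms:
            needle = form if lexicon.case_sensitive else form.casefold()
            if haystack.startswith(needle, pos):
                end = pos + len(needle)
                if word_boundaries and not _word_bounded(doc.text, pos, end):
                    continue
                if any(s < end and pos < e for s, e in taken):
                    continue
                hit = (pos, end)
                break  # forms are longest-first
        if hit is None:
            pos += 1
            continue
        start, end = hit
        etype = lexicon.best_type(doc.text[start:end])
        out.append(
            EntityAnnotation.from_document(
                ann_id=f"REC{n}",
                doc=doc,
                etype=etype or "",
                fragments=[Fragment(start, end)],
                origin=Origin.RECOMMENDATION,
                annotator=annotator,
                round=round,
            )
        )
        taken.append((start, end))
        n += 1
        pos = end
    return out


def import_predictions(
    project: Project,
    round: int,
    annotator: str,
    entities: Sequence[EntityAnnotation],
) -> tuple[int, list[tuple[str, str]]]:
    """Load externally produced entity predictions as recommendations.

    Predictions overlapping an existing annotation of the target set are
    skipped; schema or offset violations are reported per annotation.
    Returns (number added, list of (ann_id, reason) for the rest).
    """
    target = project.get_set(annotator, round)
    etypes = project.entity_type_labels()
    skipped: list[tuple[str, str]] = []
    added = 0
    e_next, _ = target.next_ids()
    for pred in entities:
        doc = project.documents.get(pred.doc_id)
        if doc is None:
            skipped.append((pred.ann_id, f"unknown document {pred.doc_id!r}"))
            continue
        if pred.etype not in etypes:
            skipped.append((pred.ann_id, f"unknown entity type {pred.etype!r}"))
            continue
        if pred.end > len(doc.text):
            skipped.append((pred.ann_id, "offsets out of range"))
            continue
        overlap = False
        for e in target.entities_in(pred.doc_id):
            for fa in pred.fragments:
                for fb in e.fragments:
                    if fa.overlap(fb) > 0:
                        overlap = True
        if overlap:
            skipped.append((pred.ann_id, "overlaps an existing annotation"))
            continue
        target.entities.append(
            EntityAnnotation.from_document(
                ann_id=f"E{e_next}",
                doc=doc,
                etype=pred.etype,
                fragments=pred.fragments,
                origin=Origin.RECOMMENDATION,
                annotator=annotator,
                round=round,
            )
        )
        e_next += 1
        added += 1
    return added, skipped
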