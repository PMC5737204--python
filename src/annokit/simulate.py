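"""Synthetic gold corpora and simulated imperfect annotators.

The generator plants typed multi-token entity mentions at word boundaries
inside token-soup documents and draws binary mention-level relations
between planted entities.  A perturbation model then emulates annotator
disagreement: misses (drops), spurious marks, boundary jitter and type
flips — the discrepancy modes that agreement analysis is meant to
surface.  Everything is driven by one explicit seeded RNG; identical
parameters and seed reproduce identical corpora byte for byte.

Document text is deliberately synthetic token soup: the test target is
offset and agreement arithmetic, not linguistic realism.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from random import Random
from typing import Sequence

from .model import (
    AnnotatedDocument,
    AnnotationSet,
    EntityAnnotation,
    Fragment,
    Granularity,
    Origin,
    Project,
    RelationAnnotation,
    RelationParticipant,
    RelationType,
    RoundStatus,
)

__all__ = [
    "PerturbationParams",
    "generate_corpus",
    "perturb_annotations",
    "build_project",
]

_SYLLABLES = [
    "ba", "cor", "din", "el", "fax", "gri", "hul", "in", "jor", "kel",
    "lom", "mir", "nev", "os", "pra", "qui", "rud", "sel", "tam", "ul",
    "vor", "wex", "yol", "zan",
]

# filler vocabulary: deterministic two/three-syllable words
_FILLER = sorted(
    {a + b for a in _SYLLABLES for b in _SYLLABLES[:12]}
    | {a + b + c for a, c in zip(_SYLLABLES, reversed(_SYLLABLES)) for b in _SYLLABLES[:6]}
)

# mention vocabulary: identifier-like tokens distinct from filler words
_MENTION_TOKENS = [f"{a}{i}" for i in range(40) for a in ("tp", "il", "gx", "dr")]


def _poisson(rng: Random, mean: float) -> int:
    """Knuth's inverse-transform Poisson sampler (small means)."""
    if mean <= 0:
        return 0
    limit = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


@dataclass(frozen=True)
class PerturbationParams:
    """Rates of the simulated annotation error modes.

    drop_prob — probability a gold entity is missed; spurious_rate —
    expected spurious entities per document (Poisson); jitter_prob /
    max_shift — probability and maximum size (characters) of boundary
    displacement; type_flip_prob — probability the type is replaced by a
    different one; relation_drop_prob — probability a surviving relation
    is still dropped; seed — RNG seed.
    """

    drop_prob: float = 0.0
    spurious_rate: float = 0.0
    jitter_prob: float = 0.0
    max_shift: int = 0
    type_flip_prob: float = 0.0
    relation_drop_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_prob", "jitter_prob", "type_flip_prob", "relation_drop_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.spurious_rate < 0 or self.max_shift < 0:
            raise ValueError("spurious_rate and max_shift must be ≥ 0")


def generate_corpus(
    n_docs: int,
    entity_types: Sequence[str],
    relation_types: Sequence[str],
    mean_entities_per_doc: float,
    mean_relations_per_doc: float,
    seed: int,
) -> tuple[dict[str, AnnotatedDocument], AnnotationSet]:
    """Build a gold-annotated corpus.

    Per document the entity count is Poisson(mean_entities_per_doc); each
    mention is 1–2 identifier tokens separated from its neighbours by 1–4
    filler tokens, so every mention sits on word boundaries.  Relations
    (Poisson mean, capped at the number of distinct entity pairs with a
    warning) are binary, mention-level, Arg1/Arg2.
    """
    if n_docs < 1 or not entity_types:
        raise ValueError("need at least one document and one entity type")
    rng = Random(seed)
    documents: dict[str, AnnotatedDocument] = {}
    gold = AnnotationSet(annotator="gold", round=1)
    e_num = r_num = 1
    for d in range(1, n_docs + 1):
        doc_id = f"d{d:04d}"
        n_ent = _poisson(rng, mean_entities_per_doc)
        pieces: list[str] = []
        planned: list[tuple[int, int, str]] = []  # start, end, mention
        cursor = 0

        def emit_filler(count: int) -> None:
            nonlocal cursor
            for _ in range(count):
                w = rng.choice(_FILLER)
                pieces.append(w)
                cursor += len(w) + 1

        emit_filler(rng.randint(1, 4))
        for _ in range(n_ent):
            n_tok = rng.randint(1, 2)
            mention = " ".join(rng.choice(_MENTION_TOKENS) for _ in range(n_tok))
            planned.append((cursor, cursor + len(mention), mention))
            pieces.append(mention)
            cursor += len(mention) + 1
            emit_filler(rng.randint(1, 4))
        text = " ".join(pieces)
        doc = AnnotatedDocument(doc_id=doc_id, text=text, metadata={"source": "synthetic"})
        documents[doc_id] = doc

        doc_entities: list[EntityAnnotation] = []
        for start, end, _mention in planned:
            ann = EntityAnnotation.from_document(
                ann_id=f"E{e_num}",
                doc=doc,
                etype=rng.choice(list(entity_types)),
                fragments=[Fragment(start, end)],
                annotator="gold",
                round=1,
            )
            e_num += 1
            doc_entities.append(ann)
            gold.entities.append(ann)

        if relation_types and len(doc_entities) >= 2:
            pairs = [
                (a.ann_id, b.ann_id)
                for i, a in enumerate(doc_entities)
                for b in doc_entities[i + 1:]
            ]
            want = _poisson(rng, mean_relations_per_doc)
            if want > len(pairs):
                warnings.warn(
                    f"{doc_id}: requested {want} relations but only "
                    f"{len(pairs)} entity pairs exist; capping",
                    stacklevel=2,
                )
                want = len(pairs)
            for arg1, arg2 in rng.sample(pairs, want):
                gold.relations.append(
                    RelationAnnotation(
                        ann_id=f"R{r_num}",
                        doc_id=doc_id,
                        rtype=rng.choice(list(relation_types)),
                        granularity=Granularity.MENTION,
                        participants=(
                            RelationParticipant(role="Arg1", entity_ref=arg1),
                            RelationParticipant(role="Arg2", entity_ref=arg2),
                        ),
                        annotator="gold",
                        round=1,
                    )
                )
                r_num += 1
    return documents, gold


_TOKEN_RE = re.compile(r"\S+")


def perturb_annotations(
    gold: AnnotationSet,
    params: PerturbationParams,
    annotator: str,
    documents: dict[str, AnnotatedDocument],
    entity_types: Sequence[str] = (),
) -> AnnotationSet:
    """Simulate one imperfect annotator over the gold standard.

    Each gold entity is independently dropped with ``drop_prob``;
    survivors get their boundaries shifted by ±U{1..max_shift} with
    ``jitter_prob`` (clamped to the document, kept non-empty, mention
    text recomputed) and their type replaced by a uniformly different
    one with ``type_flip_prob``.  Spurious entities (Poisson,
    ``spurious_rate`` per document) are added at random word-boundary
    spans.  A relation is dropped when any participant was dropped, and
    otherwise with ``relation_drop_prob``.
    """
    rng = Random(params.seed)
    types = sorted(set(entity_types) | {e.etype for e in gold.entities})
    out = AnnotationSet(annotator=annotator, round=gold.round)
    id_map: dict[str, str] = {}
    e_num = 1
    for e in gold.entities:
        if rng.random() < params.drop_prob:
            continue
        doc = documents[e.doc_id]
        start, end = e.start, e.fragments[-1].end
        if params.max_shift > 0 and rng.random() < params.jitter_prob:
            start += rng.choice((-1, 1)) * rng.randint(1, params.max_shift)
            end += rng.choice((-1, 1)) * rng.randint(1, params.max_shift)
            start = max(0, min(start, len(doc.text) - 1))
            end = max(start + 1, min(end, len(doc.text)))
        etype = e.etype
        if len(types) > 1 and rng.random() < params.type_flip_prob:
            etype = rng.choice([t for t in types if t != e.etype])
        ann = EntityAnnotation.from_document(
            ann_id=f"E{e_num}",
            doc=doc,
            etype=etype,
            fragments=[Fragment(start, end)],
            annotator=annotator,
            round=gold.round,
        )
        id_map[e.ann_id] = ann.ann_id
        out.entities.append(ann)
        e_num += 1

    if params.spurious_rate > 0:
        for doc_id in sorted(documents):
            doc = documents[doc_id]
            tokens = [m.span() for m in _TOKEN_RE.finditer(doc.text)]
            if not tokens:
                continue
            for _ in range(_poisson(rng, params.spurious_rate)):
                i = rng.randrange(len(tokens))
                j = min(i + rng.randint(0, 1), len(tokens) - 1)
                start, end = tokens[i][0], tokens[j][1]
                out.entities.append(
                    EntityAnnotation.from_document(
                        ann_id=f"E{e_num}",
                        doc=doc,
                        etype=rng.choice(types),
                        fragments=[Fragment(start, end)],
                        annotator=annotator,
                        round=gold.round,
                    )
                )
                e_num += 1

    r_num = 1
    for r in gold.relations:
        if any(p.entity_ref not in id_map for p in r.participants):
            continue
        if rng.random() < params.relation_drop_prob:
            continue
        out.relations.append(
            RelationAnnotation(
                ann_id=f"R{r_num}",
                doc_id=r.doc_id,
                rtype=r.rtype,
                granularity=r.granularity,
                participants=tuple(
                    RelationParticipant(role=p.role, entity_ref=id_map[p.entity_ref])
                    for p in r.participants
                ),
                annotator=annotator,
                round=gold.round,
            )
        )
        r_num += 1
    return out


def build_project(
    name: str,
    documents: dict[str, AnnotatedDocument],
    entity_types: Sequence[str],
    relation_types: Sequence[str],
    annotators: Sequence[str],
    sets: Sequence[AnnotationSet] = (),
) -> Project:
    """Assemble a Project around generated documents and annotator sets."""
    palette = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b"]
    project = Project(
        name=name,
        documents=dict(documents),
        entity_types=[(t, palette[i % len(palette)]) for i, t in enumerate(entity_types)],
        relation_types=[RelationType(label=t) for t in relation_types],
        annotators=list(annotators),
    )
    rounds = {s.round for s in sets} or {1}
    for r in sorted(rounds):
        project.rounds[r] = RoundStatus.OPEN
        project.round_meta[r] = {}
    for s in sets:
        project.sets[(s.annotator, s.round)] = s
    for a in project.annotators:
        for r in project.rounds:
            project.sets.setdefault((a, r), AnnotationSet(a, r))
    return project
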