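"""JSON project schema — the only format carrying the full project state
(schema, rounds, provenance, origins).  Top level:

    {"project": {...}, "documents": [...], "sets": [...]}

mirroring the domain types field for field.
"""

from __future__ import annotations

import json
from typing import Optional

from ..model import (
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
    "project_to_dict",
    "project_from_dict",
    "dumps_project",
    "loads_project",
    "set_to_dict",
    "set_from_dict",
]


def _entity_to_dict(e: EntityAnnotation) -> dict:
    return {
        "ann_id": e.ann_id,
        "doc_id": e.doc_id,
        "etype": e.etype,
        "fragments": [[f.start, f.end] for f in e.fragments],
        "mention_text": e.mention_text,
        "origin": e.origin.value,
        "annotator": e.annotator,
        "round": e.round,
    }


def _entity_from_dict(d: dict) -> EntityAnnotation:
    return EntityAnnotation(
        ann_id=d["ann_id"],
        doc_id=d["doc_id"],
        etype=d["etype"],
        fragments=tuple(Fragment(s, e) for s, e in d["fragments"]),
        mention_text=d["mention_text"],
        origin=Origin(d.get("origin", "manual")),
        annotator=d.get("annotator", ""),
        round=int(d.get("round", 1)),
    )


def _relation_to_dict(r: RelationAnnotation) -> dict:
    parts = []
    for p in r.participants:
        if p.is_mention_level:
            parts.append({"role": p.role, "entity_ref": p.entity_ref})
        else:
            parts.append({"role": p.role, "name": p.name, "etype": p.etype})
    return {
        "ann_id": r.ann_id,
        "doc_id": r.doc_id,
        "rtype": r.rtype,
        "granularity": r.granularity.value,
        "participants": parts,
        "origin": r.origin.value,
        "annotator": r.annotator,
        "round": r.round,
    }


def _relation_from_dict(d: dict) -> RelationAnnotation:
    parts = tuple(
        RelationParticipant(
            role=p["role"],
            entity_ref=p.get("entity_ref"),
            name=p.get("name"),
            etype=p.get("etype"),
        )
        for p in d["participants"]
    )
    return RelationAnnotation(
        ann_id=d["ann_id"],
        doc_id=d["doc_id"],
        rtype=d["rtype"],
        granularity=Granularity(d.get("granularity", "mention")),
        participants=parts,
        origin=Origin(d.get("origin", "manual")),
        annotator=d.get("annotator", ""),
        round=int(d.get("round", 1)),
    )


def set_to_dict(s: AnnotationSet) -> dict:
    return {
        "annotator": s.annotator,
        "round": s.round,
        "entities": [_entity_to_dict(e) for e in s.entities],
        "relations": [_relation_to_dict(r) for r in s.relations],
    }


def set_from_dict(d: dict) -> AnnotationSet:
    return AnnotationSet(
        annotator=d["annotator"],
        round=int(d["round"]),
        entities=[_entity_from_dict(e) for e in d.get("entities", [])],
        relations=[_relation_from_dict(r) for r in d.get("relations", [])],
    )


def project_to_dict(project: Project, only_sets: Optional[list] = None) -> dict:
    sets = only_sets if only_sets is not None else [
        project.sets[key] for key in sorted(project.sets)
    ]
    return {
        "project": {
            "name": project.name,
            "entity_types": [list(t) for t in project.entity_types],
            "relation_types": [
                {"label": rt.label, "arity": rt.arity, "directed": rt.directed}
                for rt in project.relation_types
            ],
            "annotators": list(project.annotators),
            "rounds": {
                str(r): {"status": st.value, "meta": project.round_meta.get(r, {})}
                for r, st in sorted(project.rounds.items())
            },
            "relation_granularity": project.relation_granularity.value,
        },
        "documents": [
            {"doc_id": d.doc_id, "text": d.text, "metadata": d.metadata}
            for d in sorted(project.documents.values(), key=lambda d: d.doc_id)
        ],
        "sets": [set_to_dict(s) for s in sets],
    }


def project_from_dict(data: dict) -> Project:
    meta = data["project"]
    project = Project(
        name=meta["name"],
        entity_types=[tuple(t) for t in meta.get("entity_types", [])],
        relation_types=[
            RelationType(rt["label"], rt.get("arity", 2), rt.get("directed", True))
            for rt in meta.get("relation_types", [])
        ],
        annotators=list(meta.get("annotators", [])),
        relation_granularity=Granularity(meta.get("relation_granularity", "mention")),
    )
    for r_str, info in meta.get("rounds", {}).items():
        r = int(r_str)
        project.rounds[r] = RoundStatus(info.get("status", "open"))
        project.round_meta[r] = dict(info.get("meta", {}))
    for d in data.get("documents", []):
        project.documents[d["doc_id"]] = AnnotatedDocument(
            doc_id=d["doc_id"], text=d["text"], metadata=dict(d.get("metadata", {}))
        )
    for s in data.get("sets", []):
        a_set = set_from_dict(s)
        project.sets[(a_set.annotator, a_set.round)] = a_set
        project.rounds.setdefault(a_set.round, RoundStatus.OPEN)
        project.round_meta.setdefault(a_set.round, {})
    return project


def dumps_project(project: Project, only_sets: Optional[list] = None) -> str:
    return json.dumps(
        project_to_dict(project, only_sets),
        ensure_ascii=False,
        indent=2,
        sort_keys=True,
    ) + "\n"


def loads_project(text: str) -> Project:
    return project_from_dict(json.loads(text))
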