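"""Consensus generation: from many annotators' sets to one final corpus.

Equivalent annotations across annotators are grouped into clusters; a
cluster enters the consensus when the fraction of annotators supporting
it reaches a configurable threshold ("at least half", "all agreed", ...),
after which manual overrides are applied — an adjudicator may force a
cluster in or out regardless of its support, e.g. excluding an annotation
that every annotator made but the guidelines reject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .agreement import MatchConfig, MatchMode, match_entity_sets
from .model import (
    AnnotationSet,
    EntityAnnotation,
    Granularity,
    Origin,
    RelationAnnotation,
    RelationParticipant,
    ValidationError,
)

__all__ = [
    "Override",
    "ConsensusConfig",
    "AnnotationCluster",
    "cluster_annotations",
    "build_consensus",
    "review_table",
    "overrides_from_table",
]

log = logging.getLogger(__name__)


class Override(str, Enum):
    FORCE_INCLUDE = "force_include"
    FORCE_EXCLUDE = "force_exclude"


@dataclass(frozen=True)
class ConsensusConfig:
    """Support threshold (fraction of annotators, in (0, 1]), the match
    mode defining 'the same annotation', and manual per-cluster
    overrides."""

    threshold: float = 0.5
    match: MatchConfig = field(default_factory=MatchConfig)
    overrides: Mapping[str, Override] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")


@dataclass
class AnnotationCluster:
    cluster_id: str
    doc_id: str
    kind: str  # "entity" | "relation"
    members: list[tuple[str, object]]  # (annotator, annotation)
    support: int  # distinct annotators

    def support_fraction(self, n_annotators: int) -> float:
        return self.support / n_annotators


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _entity_cluster_key(e: EntityAnnotation, cfg: MatchConfig) -> tuple:
    base: tuple = (e.doc_id, e.span_signature())
    return base + (e.etype,) if cfg.require_type_for_match else base


def cluster_annotations(
    sets: Sequence[AnnotationSet],
    match: MatchConfig,
    is_directed=lambda rtype: True,
) -> list[AnnotationCluster]:
    """Group equivalent annotations across the annotators of one round.

    Entities: in exact mode the cluster key is the fragment list (plus
    type when ``require_type_for_match``); in relaxed mode clusters are
    the single-linkage components of the pairwise overlap matches between
    every pair of annotators.  Relations: participants are rebound to
    their entity clusters (mention level) or compared as normalized
    (name, type) tuples (document level); relation type equality is part
    of the cluster key.  Support counts distinct annotators.
    """
    rounds = {s.round for s in sets}
    if len(rounds) > 1:
        raise ValidationError(f"sets span multiple rounds: {sorted(rounds)}")

    uf = _UnionFind()
    node_ann: dict[tuple[str, str], EntityAnnotation] = {}
    for s in sets:
        for e in s.entities:
            node_ann[(s.annotator, e.ann_id)] = e
            uf.find((s.annotator, e.ann_id))

    if match.mode is MatchMode.EXACT:
        by_key: dict[tuple, list[tuple[str, str]]] = {}
        for (annotator, ann_id), e in node_ann.items():
            by_key.setdefault(_entity_cluster_key(e, match), []).append(
                (annotator, ann_id)
            )
        for nodes in by_key.values():
            for other in nodes[1:]:
                uf.union(nodes[0], other)
    else:
        for i, sa in enumerate(sets):
            for sb in sets[i + 1:]:
                doc_ids = sorted(
                    {e.doc_id for e in sa.entities} | {e.doc_id for e in sb.entities}
                )
                for doc_id in doc_ids:
                    res = match_entity_sets(
                        sa.entities_in(doc_id), sb.entities_in(doc_id), match
                    )
                    for a_id, b_id, _ov in res.pairs:
                        uf.union((sa.annotator, a_id), (sb.annotator, b_id))

    components: dict[tuple, list[tuple[str, str]]] = {}
    for node in node_ann:
        components.setdefault(uf.find(node), []).append(node)

    def comp_sort_key(nodes: list[tuple[str, str]]) -> tuple:
        anns = [node_ann[n] for n in nodes]
        return min((a.doc_id, a.span_signature(), a.etype) for a in anns)

    clusters: list[AnnotationCluster] = []
    entity_cluster_of: dict[tuple[str, str], str] = {}
    for idx, nodes in enumerate(
        sorted(components.values(), key=comp_sort_key), start=1
    ):
        cid = f"C{idx}"
        members = sorted(
            ((annot, node_ann[(annot, aid)]) for annot, aid in nodes),
            key=lambda m: (m[0], m[1].span_signature(), m[1].ann_id),
        )
        for annot, aid in nodes:
            entity_cluster_of[(annot, aid)] = cid
        clusters.append(
            AnnotationCluster(
                cluster_id=cid,
                doc_id=members[0][1].doc_id,
                kind="entity",
                members=members,
                support=len({a for a, _ in members}),
            )
        )

    # relations: key on rtype plus cluster-rebound participants
    rel_groups: dict[tuple, list[tuple[str, RelationAnnotation]]] = {}
    for s in sets:
        for r in s.relations:
            if r.granularity is Granularity.DOCUMENT:
                key = (r.doc_id, r.rtype, tuple(sorted(p.name_key() for p in r.participants)))
            else:
                mapped = []
                for p in r.participants:
                    cid = entity_cluster_of.get((s.annotator, p.entity_ref))
                    if cid is None:
                        raise ValidationError(
                            f"{r.ann_id}: dangling entity reference {p.entity_ref!r}"
                        )
                    mapped.append((p.role, cid))
                if is_directed(r.rtype):
                    key = (r.doc_id, r.rtype, tuple(sorted(mapped)))
                else:
                    key = (r.doc_id, r.rtype, tuple(sorted(c for _role, c in mapped)))
            rel_groups.setdefault(key, []).append((s.annotator, r))

    for idx, key in enumerate(sorted(rel_groups, key=repr), start=1):
        members = sorted(rel_groups[key], key=lambda m: (m[0], m[1].ann_id))
        clusters.append(
            AnnotationCluster(
                cluster_id=f"CR{idx}",
                doc_id=members[0][1].doc_id,
                kind="relation",
                members=members,
                support=len({a for a, _ in members}),
            )
        )
    return clusters


def _representative_entity(members: list[tuple[str, EntityAnnotation]]):
    """Most frequent exact shape; ties → longest total span → smallest
    start.  Type: majority among members, ties → lexicographically first."""
    shape_counts: dict[tuple, int] = {}
    for _a, e in members:
        shape_counts[e.span_signature()] = shape_counts.get(e.span_signature(), 0) + 1
    best_shape = min(
        shape_counts,
        key=lambda s: (
            -shape_counts[s],
            -sum(e - st for st, e in s),
            s[0][0],
            s,
        ),
    )
    exemplar = next(e for _a, e in members if e.span_signature() == best_shape)
    type_counts: dict[str, int] = {}
    for _a, e in members:
        type_counts[e.etype] = type_counts.get(e.etype, 0) + 1
    best_type = min(type_counts, key=lambda t: (-type_counts[t], t))
    n_top = sum(1 for c in type_counts.values() if c == type_counts[best_type])
    if n_top > 1:
        log.warning(
            "type tie in cluster at %s %s: chose %r among %s",
            exemplar.doc_id,
            best_shape,
            best_type,
            sorted(type_counts),
        )
    return exemplar, best_type


def build_consensus(
    clusters: Sequence[AnnotationCluster],
    cfg: ConsensusConfig,
    n_annotators: int,
    round: int = 0,
) -> AnnotationSet:
    """Apply the support threshold and overrides; emit the consensus set.

    A cluster is kept iff support/n_annotators ≥ threshold, then manual
    overrides win in both directions (a forced exclusion removes even a
    unanimously supported annotation).  Mention-level relations survive
    only when every participant entity cluster was kept; their
    participants are rebound to the representative entities.
    """
    if n_annotators < 1:
        raise ValueError("n_annotators must be ≥ 1")

    def kept(c: AnnotationCluster) -> bool:
        ov = cfg.overrides.get(c.cluster_id)
        if ov is not None:
            return Override(ov) is Override.FORCE_INCLUDE
        return c.support_fraction(n_annotators) >= cfg.threshold

    out = AnnotationSet(annotator="consensus", round=round)
    entity_rep: dict[str, str] = {}  # cluster_id -> consensus ann_id
    member_cluster: dict[tuple[str, str], str] = {}
    e_count = 0
    for c in clusters:
        if c.kind != "entity":
            continue
        for annot, ann in c.members:
            member_cluster[(annot, ann.ann_id)] = c.cluster_id
        if not kept(c):
            continue
        exemplar, etype = _representative_entity(c.members)
        e_count += 1
        ann_id = f"E{e_count}"
        entity_rep[c.cluster_id] = ann_id
        out.entities.append(
            EntityAnnotation(
                ann_id=ann_id,
                doc_id=exemplar.doc_id,
                etype=etype,
                fragments=exemplar.fragments,
                mention_text=exemplar.mention_text,
                origin=Origin.MANUAL,
                annotator="consensus",
                round=round,
            )
        )

    r_count = 0
    for c in clusters:
        if c.kind != "relation" or not kept(c):
            continue
        annot, exemplar = c.members[0]
        if exemplar.granularity is Granularity.MENTION:
            new_parts = []
            orphaned = False
            for p in exemplar.participants:
                cid = member_cluster.get((annot, p.entity_ref))
                rep = entity_rep.get(cid or "")
                if rep is None:
                    orphaned = True
                    break
                new_parts.append(RelationParticipant(role=p.role, entity_ref=rep))
            if orphaned:
                log.info(
                    "dropping consensus relation cluster %s: a participant "
                    "entity did not reach consensus",
                    c.cluster_id,
                )
                continue
            participants = tuple(new_parts)
        else:
            participants = exemplar.participants
        r_count += 1
        out.relations.append(
            RelationAnnotation(
                ann_id=f"R{r_count}",
                doc_id=exemplar.doc_id,
                rtype=exemplar.rtype,
                granularity=exemplar.granularity,
                participants=participants,
                origin=Origin.MANUAL,
                annotator="consensus",
                round=round,
            )
        )
    return out


def review_table(
    clusters: Sequence[AnnotationCluster],
    cfg: ConsensusConfig,
    n_annotators: int,
) -> str:
    """Offline adjudication table (TSV): one row per cluster with its
    support and the decision the current config would take.  Edit the
    decision column and feed the file back via overrides_from_table."""
    lines = [
        "cluster_id\tdoc_id\tkind\trepresentative\tsupport\tsupport_fraction\tdecision"
    ]
    for c in clusters:
        ov = cfg.overrides.get(c.cluster_id)
        if ov is not None:
            decision = Override(ov).value
        else:
            decision = (
                "include"
                if c.support_fraction(n_annotators) >= cfg.threshold
                else "exclude"
            )
        if c.kind == "entity":
            _ex, etype = _representative_entity(c.members)
            ann = c.members[0][1]
            rep = f"{etype}:{ann.mention_text}"
        else:
            ann = c.members[0][1]
            parts = ",".join(
                p.entity_ref if p.is_mention_level else f"{p.name}|{p.etype}"
                for p in ann.participants
            )
            rep = f"{ann.rtype}({parts})"
        frac = c.support_fraction(n_annotators)
        lines.append(
            f"{c.cluster_id}\t{c.doc_id}\t{c.kind}\t{rep}\t{c.support}\t{frac:.3f}\t{decision}"
        )
    return "\n".join(lines) + "\n"


def overrides_from_table(tsv: str) -> dict[str, Override]:
    """Parse an edited review table back into an overrides map; only
    explicit force_include / force_exclude decisions become overrides."""
    overrides: dict[str, Override] = {}
    for i, line in enumerate(tsv.splitlines()):
        if i == 0 or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 7:
            continue
        decision = fields[6].strip()
        if decision in (Override.FORCE_INCLUDE.value, Override.FORCE_EXCLUDE.value):
            overrides[fields[0]] = Override(decision)
    return overrides
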