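"""Inter-annotator (IAA) and inter-round (IRA) agreement.

Agreement between two annotation sets is measured with precision, recall
and F-score over a one-to-one matching of their annotations:

    precision = |matched| / |A|        (A is the precision side)
    recall    = |matched| / |B|
    F         = 2 P R / (P + R)

Entity matching is either *exact* (identical fragment lists) or *relaxed*
(spans overlap by at least a user-chosen minimum number of characters).
Matched pairs feed a per-type agreement matrix whose diagonal gives the
per-type true positives and whose margins (including the unmatched "∅"
row/column) give false positives and false negatives — off-diagonal cells
expose type confusions between annotators or across rounds.

The relaxed matching contract: the lexicographically-first
maximum-cardinality one-to-one matching under a highest-overlap-first,
side-symmetric edge order.  It is deterministic, invariant under swapping
the two sides (so swapping transposes the matrix exactly), its size is
non-increasing in the overlap threshold, and it always attains the
maximum matched-pair count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .model import (
    AnnotationSet,
    EntityAnnotation,
    Granularity,
    Project,
    RelationAnnotation,
    ValidationError,
)

__all__ = [
    "MatchMode",
    "MatchConfig",
    "MatchResult",
    "AgreementMatrix",
    "Metrics",
    "AgreementReport",
    "span_overlap",
    "match_entity_sets",
    "match_relation_sets",
    "build_agreement_matrix",
    "prf_from_counts",
    "percent",
    "compute_iaa",
    "compute_ira",
    "multi_annotator_summary",
    "MultiAnnotatorSummary",
]

UNMATCHED = "∅"


class MatchMode(str, Enum):
    EXACT = "exact"
    RELAXED = "relaxed"


@dataclass(frozen=True)
class MatchConfig:
    """How two annotations are considered 'the same annotation'.

    ``min_overlap`` (relaxed mode only) is the user-specified minimum
    number of shared characters.  By default the pairing ignores the type
    label: type agreement is assessed through the agreement matrix, so a
    type confusion shows up as an off-diagonal cell rather than as two
    unmatched annotations.  ``require_type_for_match`` enables the
    stricter behaviour.
    """

    mode: MatchMode = MatchMode.EXACT
    min_overlap: int = 1
    require_type_for_match: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", MatchMode(self.mode))
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be ≥ 1")


@dataclass
class MatchResult:
    """One-to-one pairing of two annotation lists.

    Each ann_id appears at most once across pairs ∪ unmatched on its side;
    together they cover each side exactly.
    """

    pairs: list[tuple[str, str, int]] = field(default_factory=list)
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    def matched_a(self) -> set[str]:
        return {a for a, _b, _o in self.pairs}

    def matched_b(self) -> set[str]:
        return {b for _a, b, _o in self.pairs}


def span_overlap(a: EntityAnnotation, b: EntityAnnotation) -> int:
    """Total number of characters shared by two (possibly discontinuous)
    mentions: the sum over fragment pairs of interval intersections."""
    if a.doc_id != b.doc_id:
        raise ValidationError(
            f"cannot overlap annotations of different documents "
            f"({a.doc_id!r} vs {b.doc_id!r})"
        )
    return sum(fa.overlap(fb) for fa in a.fragments for fb in b.fragments)


# ---------------------------------------------------------------------------
# Canonical one-to-one matching
# ---------------------------------------------------------------------------


def _max_matching_size(
    a_nodes: Sequence[str], adj: Mapping[str, Sequence[str]]
) -> int:
    """Maximum bipartite matching size (Kuhn's augmenting paths)."""
    match_b: dict[str, str] = {}

    def try_augment(a: str, seen: set[str]) -> bool:
        for b in adj.get(a, ()):
            if b in seen:
                continue
            seen.add(b)
            if b not in match_b or try_augment(match_b[b], seen):
                match_b[b] = a
                return True
        return False

    size = 0
    for a in a_nodes:
        if try_augment(a, set()):
            size += 1
    return size


def _canonical_matching(
    edges: list[tuple[str, str, int, tuple, tuple]],
) -> list[tuple[str, str, int]]:
    """Lexicographically-first maximum-cardinality matching.

    *edges* are (a_id, b_id, weight, a_key, b_key); the edge order is
    (weight desc, unordered {a_key, b_key}), which is invariant under
    swapping the two sides.  Walking edges in that order, an edge is kept
    iff forcing it still allows a maximum-cardinality completion;
    otherwise it is discarded for good.
    """
    if not edges:
        return []

    def order_key(e: tuple) -> tuple:
        _a, _b, w, ka, kb = e
        lo, hi = (ka, kb) if ka <= kb else (kb, ka)
        return (-w, lo, hi, ka)

    pool = sorted(edges, key=order_key)
    adj: dict[str, list[str]] = {}
    for a, b, _w, _ka, _kb in pool:
        adj.setdefault(a, []).append(b)
    target = _max_matching_size(sorted(adj), adj)

    chosen: list[tuple[str, str, int]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    remaining = pool
    while remaining and len(chosen) < target:
        edge, rest = remaining[0], remaining[1:]
        a, b, w, _ka, _kb = edge
        rest = [e for e in rest if e[0] != a or e[1] != b]
        # completion size if (a, b) is forced
        sub_adj: dict[str, list[str]] = {}
        for ea, eb, _ew, _k1, _k2 in rest:
            if ea != a and eb != b:
                sub_adj.setdefault(ea, []).append(eb)
        if 1 + len(chosen) + _max_matching_size(sorted(sub_adj), sub_adj) == target:
            chosen.append((a, b, w))
            used_a.add(a)
            used_b.add(b)
            remaining = [
                e for e in rest if e[0] not in used_a and e[1] not in used_b
            ]
        else:
            remaining = rest
    return chosen


def _entity_sort_key(e: EntityAnnotation) -> tuple:
    return (e.doc_id, e.span_signature(), e.etype, e.ann_id)


def match_entity_sets(
    A: Sequence[EntityAnnotation],
    B: Sequence[EntityAnnotation],
    cfg: MatchConfig,
) -> MatchResult:
    """Pair the entity annotations of two sets over one document.

    Exact mode pairs annotations with identical fragment lists (and
    identical type if ``require_type_for_match``); duplicates are matched
    one-to-one.  Relaxed mode pairs annotations whose spans share at least
    ``min_overlap`` characters, via the canonical maximum matching.
    """
    docs = {e.doc_id for e in A} | {e.doc_id for e in B}
    if len(docs) > 1:
        raise ValidationError(
            f"match_entity_sets expects annotations of one document, got {sorted(docs)}"
        )
    result = MatchResult()
    if cfg.mode is MatchMode.EXACT:
        def key(e: EntityAnnotation) -> tuple:
            base: tuple = e.span_signature()
            return (base, e.etype) if cfg.require_type_for_match else (base,)

        grouped_a: dict[tuple, list[EntityAnnotation]] = {}
        grouped_b: dict[tuple, list[EntityAnnotation]] = {}
        for e in sorted(A, key=_entity_sort_key):
            grouped_a.setdefault(key(e), []).append(e)
        for e in sorted(B, key=_entity_sort_key):
            grouped_b.setdefault(key(e), []).append(e)
        matched_a: set[str] = set()
        matched_b: set[str] = set()
        for k in sorted(grouped_a, key=repr):
            for ea, eb in zip(grouped_a[k], grouped_b.get(k, [])):
                result.pairs.append((ea.ann_id, eb.ann_id, ea.total_length()))
                matched_a.add(ea.ann_id)
                matched_b.add(eb.ann_id)
        result.unmatched_a = [e.ann_id for e in A if e.ann_id not in matched_a]
        result.unmatched_b = [e.ann_id for e in B if e.ann_id not in matched_b]
        return result

    edges = []
    for ea in A:
        for eb in B:
            if cfg.require_type_for_match and ea.etype != eb.etype:
                continue
            ov = span_overlap(ea, eb)
            if ov >= cfg.min_overlap:
                edges.append(
                    (
                        ea.ann_id,
                        eb.ann_id,
                        ov,
                        _entity_sort_key(ea),
                        _entity_sort_key(eb),
                    )
                )
    result.pairs = _canonical_matching(edges)
    ma, mb = result.matched_a(), result.matched_b()
    result.unmatched_a = [e.ann_id for e in A if e.ann_id not in ma]
    result.unmatched_b = [e.ann_id for e in B if e.ann_id not in mb]
    return result


def _relation_sort_key(r: RelationAnnotation) -> tuple:
    parts = tuple(
        sorted(
            (p.role, p.entity_ref or "", p.name or "", p.etype or "")
            for p in r.participants
        )
    )
    return (r.doc_id, parts, r.rtype, r.ann_id)


def match_relation_sets(
    A: Sequence[RelationAnnotation],
    B: Sequence[RelationAnnotation],
    entities_a: Sequence[EntityAnnotation],
    entities_b: Sequence[EntityAnnotation],
    entity_match: MatchResult,
    granularity: Granularity,
    is_directed: Callable[[str], bool] = lambda rtype: True,
    case_sensitive: bool = True,
) -> MatchResult:
    """Pair relation annotations of two sets.

    Mention level: relations pair when each participant of one is
    entity-matched (through *entity_match*) to a participant of the other;
    for directed relation types the roles must correspond, undirected
    types accept any participant permutation.  Document level: relations
    pair when their sorted (name, type) participant tuples are equal after
    NFC normalization and trimming.  Pairing does not require equal
    relation types — a re-typed relation still pairs and lands in an
    off-diagonal matrix cell.  Same-type candidate pairs are preferred.
    """
    granularity = Granularity(granularity)
    ea_index = {e.ann_id: e for e in entities_a}
    eb_index = {e.ann_id: e for e in entities_b}
    a_to_b = {a: b for a, b, _o in entity_match.pairs}

    def compatible(ra: RelationAnnotation, rb: RelationAnnotation) -> bool:
        if ra.doc_id != rb.doc_id or len(ra.participants) != len(rb.participants):
            return False
        if granularity is Granularity.DOCUMENT:
            pa = sorted(p.name_key(case_sensitive) for p in ra.participants)
            pb = sorted(p.name_key(case_sensitive) for p in rb.participants)
            return pa == pb
        for p in ra.participants:
            if p.entity_ref not in ea_index:
                raise ValidationError(
                    f"{ra.ann_id}: dangling entity reference {p.entity_ref!r}"
                )
        for p in rb.participants:
            if p.entity_ref not in eb_index:
                raise ValidationError(
                    f"{rb.ann_id}: dangling entity reference {p.entity_ref!r}"
                )
        mapped = {}
        for p in ra.participants:
            ref = a_to_b.get(p.entity_ref)
            if ref is None:
                return False
            mapped[p.role] = ref
        directed = is_directed(ra.rtype) or is_directed(rb.rtype)
        if directed:
            by_role = {p.role: p.entity_ref for p in rb.participants}
            if set(by_role) != set(mapped):
                return False
            return all(by_role[role] == ref for role, ref in mapped.items())
        return sorted(mapped.values()) == sorted(
            p.entity_ref for p in rb.participants
        )

    edges = []
    for ra in A:
        for rb in B:
            if compatible(ra, rb):
                weight = 2 if ra.rtype == rb.rtype else 1
                edges.append(
                    (
                        ra.ann_id,
                        rb.ann_id,
                        weight,
                        _relation_sort_key(ra),
                        _relation_sort_key(rb),
                    )
                )
    result = MatchResult(pairs=_canonical_matching(edges))
    ma, mb = result.matched_a(), result.matched_b()
    result.unmatched_a = [r.ann_id for r in A if r.ann_id not in ma]
    result.unmatched_b = [r.ann_id for r in B if r.ann_id not in mb]
    return result


# ---------------------------------------------------------------------------
# Agreement matrix and metrics
# ---------------------------------------------------------------------------


class AgreementMatrix:
    """Per-type confusion counts between two annotation sets.

    Rows are indexed by A's type, columns by B's type; the sentinel "∅"
    column holds A-annotations left unmatched and the "∅" row holds
    B-annotations left unmatched.  TP(t) is the diagonal cell; FP(t) is
    the rest of row t (the sum of the horizontal values); FN(t) the rest
    of column t (the sum of the vertical values).
    """

    def __init__(self, labels: Optional[Iterable[str]] = None) -> None:
        self._labels: list[str] = []
        self.cells: dict[tuple[str, str], int] = {}
        for lb in labels or ():
            self._ensure(lb)

    def _ensure(self, label: str) -> None:
        if label != UNMATCHED and label not in self._labels:
            self._labels.append(label)

    @property
    def labels(self) -> list[str]:
        return [*self._labels, UNMATCHED]

    def add(self, row: str, col: str, count: int = 1) -> None:
        if row == UNMATCHED and col == UNMATCHED:
            raise ValueError("the (∅, ∅) cell is identically zero")
        self._ensure(row)
        self._ensure(col)
        self.cells[(row, col)] = self.cells.get((row, col), 0) + count

    def cell(self, row: str, col: str) -> int:
        return self.cells.get((row, col), 0)

    def row_sum(self, label: str) -> int:
        return sum(v for (r, _c), v in self.cells.items() if r == label)

    def col_sum(self, label: str) -> int:
        return sum(v for (_r, c), v in self.cells.items() if c == label)

    def tp(self, label: str) -> int:
        return self.cell(label, label)

    def fp(self, label: str) -> int:
        return self.row_sum(label) - self.tp(label)

    def fn(self, label: str) -> int:
        return self.col_sum(label) - self.tp(label)

    def total_a(self) -> int:
        """Number of A-side annotations accounted for."""
        return sum(v for (r, _c), v in self.cells.items() if r != UNMATCHED)

    def total_b(self) -> int:
        return sum(v for (_r, c), v in self.cells.items() if c != UNMATCHED)

    def transposed(self) -> "AgreementMatrix":
        out = AgreementMatrix(self._labels)
        for (r, c), v in self.cells.items():
            out.cells[(c, r)] = v
        return out

    def to_rows(self) -> list[list]:
        """Labeled grid (header row + one row per label) for TSV export."""
        labels = self.labels
        rows: list[list] = [["type", *labels]]
        for r in labels:
            rows.append([r, *[self.cell(r, c) for c in labels]])
        return rows


def percent(x: float) -> int:
    """Nearest integer percent, half up (0.745 → 75)."""
    return int(Decimal(str(x * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    fn: int

    def as_percents(self) -> tuple[int, int, int]:
        return percent(self.precision), percent(self.recall), percent(self.f_score)


def prf_from_counts(tp: int, fp: int, fn: int) -> Metrics:
    """Precision, recall and F-score from a contingency triple.

    Conventions for degenerate denominators: with nothing annotated on
    either side (tp=fp=fn=0) agreement is perfect (all metrics 1); a zero
    denominator with other counts present yields 0 for that metric.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == fp == fn == 0:
        return Metrics(1.0, 1.0, 1.0, 0, 0, 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p, r, f, tp, fp, fn)


def build_agreement_matrix(
    match: MatchResult,
    A: Sequence[EntityAnnotation] | Sequence[RelationAnnotation],
    B: Sequence[EntityAnnotation] | Sequence[RelationAnnotation],
    matrix: Optional[AgreementMatrix] = None,
) -> AgreementMatrix:
    """Fill (or extend) an agreement matrix from a match result: each pair
    increments cell (type(a), type(b)); unmatched annotations increment
    the ∅ margins."""

    def type_of(ann) -> str:
        return ann.etype if isinstance(ann, EntityAnnotation) else ann.rtype

    a_index = {ann.ann_id: ann for ann in A}
    b_index = {ann.ann_id: ann for ann in B}
    m = matrix if matrix is not None else AgreementMatrix()
    for a_id, b_id, _ov in match.pairs:
        m.add(type_of(a_index[a_id]), type_of(b_index[b_id]))
    for a_id in match.unmatched_a:
        m.add(type_of(a_index[a_id]), UNMATCHED)
    for b_id in match.unmatched_b:
        m.add(UNMATCHED, type_of(b_index[b_id]))
    return m


@dataclass
class AgreementReport:
    """Per-type and micro-averaged metrics plus the full matrix."""

    scope: str  # "entities" | "relations"
    comparison: tuple[str, str]  # identifiers of the A and B sides
    matrix: AgreementMatrix
    per_type: dict[str, Metrics]
    overall: Metrics

    def to_dict(self) -> dict:
        def metr(m: Metrics) -> dict:
            return {
                "precision": m.precision,
                "recall": m.recall,
                "f_score": m.f_score,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
            }

        return {
            "scope": self.scope,
            "comparison": list(self.comparison),
            "labels": self.matrix.labels,
            "matrix": {f"{r}\t{c}": v for (r, c), v in sorted(self.matrix.cells.items())},
            "per_type": {t: metr(m) for t, m in sorted(self.per_type.items())},
            "overall": metr(self.overall),
        }


def report_from_matrix(
    matrix: AgreementMatrix, scope: str, comparison: tuple[str, str]
) -> AgreementReport:
    per_type = {
        t: prf_from_counts(matrix.tp(t), matrix.fp(t), matrix.fn(t))
        for t in matrix.labels
        if t != UNMATCHED
    }
    diag = sum(matrix.tp(t) for t in matrix.labels if t != UNMATCHED)
    overall = prf_from_counts(
        diag, matrix.total_a() - diag, matrix.total_b() - diag
    )
    return AgreementReport(scope, comparison, matrix, per_type, overall)


# ---------------------------------------------------------------------------
# Corpus-level agreement
# ---------------------------------------------------------------------------


def _agree_sets(
    set_a: AnnotationSet,
    set_b: AnnotationSet,
    cfg: MatchConfig,
    granularity: Granularity,
    is_directed: Callable[[str], bool],
    label_a: str,
    label_b: str,
) -> tuple[AgreementReport, AgreementReport]:
    ent_matrix = AgreementMatrix()
    rel_matrix = AgreementMatrix()
    doc_ids = sorted(
        {e.doc_id for e in set_a.entities}
        | {e.doc_id for e in set_b.entities}
        | {r.doc_id for r in set_a.relations}
        | {r.doc_id for r in set_b.relations}
    )
    for doc_id in doc_ids:
        ea, eb = set_a.entities_in(doc_id), set_b.entities_in(doc_id)
        ra, rb = set_a.relations_in(doc_id), set_b.relations_in(doc_id)
        ematch = match_entity_sets(ea, eb, cfg)
        build_agreement_matrix(ematch, ea, eb, ent_matrix)
        if ra or rb:
            rmatch = match_relation_sets(
                ra, rb, ea, eb, ematch, granularity, is_directed
            )
            build_agreement_matrix(rmatch, ra, rb, rel_matrix)
    comparison = (label_a, label_b)
    return (
        report_from_matrix(ent_matrix, "entities", comparison),
        report_from_matrix(rel_matrix, "relations", comparison),
    )


def compute_iaa(
    project: Project,
    round: int,
    annotator_a: str,
    annotator_b: str,
    cfg: MatchConfig,
) -> tuple[AgreementReport, AgreementReport]:
    """Inter-annotator agreement in one round: annotator_a supplies the
    precision side, annotator_b the recall side.  Returns the entity and
    relation reports (corpus-level matrices aggregated per document)."""
    set_a = project.get_set(annotator_a, round)
    set_b = project.get_set(annotator_b, round)
    return _agree_sets(
        set_a,
        set_b,
        cfg,
        project.relation_granularity,
        project.is_directed,
        f"{annotator_a}@r{round}",
        f"{annotator_b}@r{round}",
    )


def compute_ira(
    project: Project,
    annotator: str,
    round_i: int,
    round_j: int,
    cfg: MatchConfig,
) -> tuple[AgreementReport, AgreementReport]:
    """Inter-round agreement of a single annotator: how consistent their
    annotation pattern stayed between two rounds.  The later round is the
    precision side; off-diagonal matrix cells expose re-typings."""
    earlier, later = sorted((round_i, round_j))
    set_b = project.get_set(annotator, earlier)
    set_a = project.get_set(annotator, later)
    return _agree_sets(
        set_a,
        set_b,
        cfg,
        project.relation_granularity,
        project.is_directed,
        f"{annotator}@r{later}",
        f"{annotator}@r{earlier}",
    )


@dataclass
class MultiAnnotatorSummary:
    pairwise: list[tuple[tuple[str, str], AgreementReport, AgreementReport]]
    macro_f_entities: float
    macro_f_relations: float


def multi_annotator_summary(
    project: Project, round: int, cfg: MatchConfig
) -> MultiAnnotatorSummary:
    """All unordered annotator pairs in a round, plus the macro-averaged
    overall F (mean of the pairwise overall F-scores)."""
    present = [a for a in project.annotators if (a, round) in project.sets]
    if len(present) < 2:
        raise ValidationError(
            f"round {round} has {len(present)} annotation set(s); need ≥2"
        )
    pairwise = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            ents, rels = compute_iaa(project, round, a, b, cfg)
            pairwise.append(((a, b), ents, rels))
    macro_e = sum(e.overall.f_score for _p, e, _r in pairwise) / len(pairwise)
    macro_r = sum(r.overall.f_score for _p, _e, r in pairwise) / len(pairwise)
    return MultiAnnotatorSummary(pairwise, macro_e, macro_r)
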