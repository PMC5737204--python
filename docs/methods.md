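# Methods

This note records the models and procedures `annokit` implements, the
choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Data model

Documents are immutable Unicode strings; every offset counts code
points, is 0-based and half-open. Entity mentions may be discontinuous
(ordered, pairwise-disjoint fragments); the stored mention text is the
space-joined concatenation of the fragment substrings, and every ingest
path verifies it against the document (an optional repair mode rebuilds
it from the offsets instead). Overlapping mentions by one annotator are
legal — partial-word tagging and nested/overlapping marks occur in real
schemas — so no reader or operation assumes disjointness.

Relations carry ≥2 role-labelled participants in exactly one of two
anchor forms, fixed per project: **mention level** (participants are
entity annotations of the same annotator, round and document) or
**document level** (participants are (name, type) pairs; the
(participants, type) tuple is unique per document, enforced on every
ingest path). Switching granularity is refused while any relation
exists, because the two forms are not convertible in place. Relation
types declare arity and directedness in the schema; binary directed is
the default and the tested configuration, n-ary is accepted
structurally.

Rounds are global integers with open/finalized status. *Copy* hands one
annotator's set to another as an independent deep copy (fresh ids,
relation references remapped); *duplicate* checkpoints a whole round as
an ordinary round tagged `checkpoint_of` in its metadata — no separate
storage tier. *Finalize* flips every remaining recommendation to an
accepted manual annotation and reports the count; a second finalize is
an error and origins stay manual.

## Agreement

Two sets are compared per document and aggregated into corpus-level
per-type matrices. The first-named set is the precision side throughout
(for inter-round agreement, the later round), which makes off-diagonal
cells read as "the precision side now says *row* where the recall side
said *column*"; the headline F is orientation-free.

**Matching.** Exact mode pairs identical fragment lists, duplicates
one-to-one. Relaxed mode pairs annotations whose spans share at least
`min_overlap` characters (for discontinuous mentions, overlap is the
sum of fragment-pair intersections, not the convex hull — the hull
would credit characters neither mention covers). The matching contract
is the *lexicographically-first maximum-cardinality one-to-one
matching* under a highest-overlap-first, side-symmetric edge order: an
edge is kept iff forcing it still permits a maximum-cardinality
completion, otherwise it is discarded. Three properties follow by
construction and are property-tested:

- it always attains the matched-pair count an exhaustive enumeration
  finds (a plain greedy-by-overlap scan does not: a high-overlap pair
  can block two lower-overlap pairs);
- it is invariant under swapping the two sides, so swapping transposes
  the agreement matrix exactly and exchanges precision with recall
  while preserving F;
- its size is monotone non-increasing in `min_overlap` (raising the
  threshold only deletes candidate edges), and never below the
  exact-match pair count.

The edge-ordering cost is O(E² · V) per document in the worst case via
Kuhn's algorithm on each prefix; per-document annotation counts in
annotation projects are small enough that this is negligible.

**Type handling.** Pairing ignores the type label by default: a type
confusion is one matched pair in an off-diagonal cell, which is the
only reading under which "FP = sum of the horizontal values" includes
re-typings. `require_type_for_match` gives the stricter behaviour.
Relation pairing likewise ignores the relation type but prefers
same-type candidates when several relation pairs share participants.
For directed relation types roles must correspond through the entity
matching; undirected types accept any participant permutation.
Document-level participants compare after NFC normalization and
whitespace trim, case-sensitive by default with a case-folding switch.

**Metrics.** P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R). Degenerate
conventions: two empty sides agree perfectly (all metrics 1) — agreement
on nothing is agreement; a zero denominator alongside non-zero counts
yields 0 for that metric. Display rounding is nearest integer percent,
half up. With more than two annotators the summary is all unordered
pairwise reports plus the macro-average (mean of pairwise overall F);
micro-averaging across pairs would double-count annotators that appear
in many pairs.

## Consensus

Entities cluster by identical spans in exact mode, and by single-linkage
over the pairwise relaxed matches between every annotator pair in
relaxed mode — single linkage is the only order-independent grouping
consistent with pairwise overlap matching; its known failure mode
(chains merging distant spans) is mitigated by representative
selection. Relations cluster by relation type plus participants rebound
to their entity clusters (mention level) or normalized name/type tuples
(document level). Support counts distinct annotators; when linkage puts
two annotations of one annotator into one cluster, both stay visible as
members but support still counts the annotator once.

A cluster enters the consensus iff support/n ≥ threshold, where n is
the number of annotators registered for the round (not only those who
touched the document — the threshold reads as a percentage of users).
Manual overrides then win in both directions; a forced exclusion
removes even a unanimously supported annotation. The representative is
the most frequent exact shape (ties: longest total span, then smallest
start); its type is the member majority (ties: lexicographically first,
logged). Mention-level relations survive only if every participant
cluster was kept — orphaned relations are dropped and logged rather
than dragging non-consensus entities in. Limit semantics are tested:
threshold → 0⁺ is the union, threshold 1.0 the intersection, and size
is monotone non-increasing in the threshold.

Adjudication happens offline: `review_table` emits a TSV of clusters
with support and the pending decision; edited `force_include` /
`force_exclude` rows read back as the overrides map.

## Recommendations

The lexicon maps surface forms to type frequency tables. Harvesting
tallies only manual-origin mentions — pending recommendations and raw
imports are not yet human-asserted ground truth. Generation scans each
document left to right, longest form first, requiring word boundaries
(neighbouring characters non-alphanumeric or string edge; switchable
off for unspaced scripts), and skips candidates overlapping existing
annotations or earlier recommendations; the emitted type is the form's
highest-frequency type, ties alphabetical. Matching is case-sensitive
by default. All of this is deterministic: same document, lexicon and
existing annotations give the identical list. External predictions
import as recommendations, skipping overlaps with existing annotations
and reporting schema violations per annotation. Relation
recommendations are out of scope.

## Synthetic corpora

The generator plants 1–2-token identifier-like mentions separated by
1–4 filler tokens of syllable soup, so every mention sits on word
boundaries; entity counts per document are Poisson with configurable
mean, types uniform over the schema; binary mention-level relations are
drawn uniformly over distinct planted pairs (Poisson mean, capped at
the available pairs with a warning). One `random.Random(seed)` drives
everything; no global state. The perturbation model applies, per
entity, an independent miss (drop probability), boundary jitter
(each boundary shifted by ±U{1..max_shift}, clamped to the document
and kept non-empty, mention text recomputed), and a type flip to a
uniformly different label; spurious entities arrive at Poisson rate per
document on random word-boundary token spans; relations drop when a
participant dropped, plus an independent relation drop rate.

Defaults used in the tests and the acceptance script: 100 documents at
mean 5 entities/document (≈500 gold mentions, large enough that a 20%
miss rate is recovered within its central 99% binomial interval while
the whole suite runs in seconds) and 20% independent miss rates for the
two simulated annotators — a disagreement level typical of a first
annotation round.

What passing these tests shows: the offset, matching, matrix and
consensus arithmetic is correct on data whose ground truth is known
exactly. What it does not show: behaviour on real language (the token
soup has no ambiguity, no nested syntax, no tokenization edge cases
beyond word boundaries), realistic disagreement structure (real
annotators err systematically, not independently), or annotator
learning across rounds, which the simulator deliberately does not
model.

## I/O

BRAT/BioNLP standoff, BioC inline XML, TSV dialects and a JSON project
schema. Offset or mention-text violations raise with a line/element
locator; constructs outside the data model (events, attributes,
normalizations, notes) are skipped loudly into the import report, never
silently. BioC annotation offsets are absolute document offsets, with
an optional strict mode re-validating against passage bounds; document
text is reconstructed by placing passages at their offsets, gaps
becoming spaces. The standoff TSV export is a single self-describing
nine-column table covering entities and relations (offsets `s:e[;s:e]`
or `-`; participants `role:ann_id` or `role:name|etype`); the JSON
schema mirrors the domain types and is the only format carrying rounds
and origins; the inline TSV view wraps mentions as
`[[type|ann_id:mention]]`, nested marks opened in (start, −length)
order — it is a rendering, not a round-trippable store. All writers
order output by (doc_id, start, ann_id) and are byte-deterministic;
everything is UTF-8. Round-trip fidelity (annotation content modulo
ids) is tested for BRAT→BioC→BRAT and JSON→standoff-TSV→JSON.

## Known limitations

- Chance-corrected agreement coefficients (κ, α) are not provided; the
  analysis is precision/recall/F only.
- Greedy single-linkage consensus clusters can chain across annotators
  in dense overlap regions; exact mode or a higher `min_overlap` is the
  remedy.
- n-ary and undirected relations are modelled but only binary directed
  relations are exercised end-to-end by the simulator.
- BioNLP event semantics (triggers, nested arguments) are not imported.
- The CLI persists whole projects as one JSON document; very large
  corpora would want a sharded store.
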