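# annokit

Computational back end for collaborative text-corpus annotation projects,
aimed at teams producing gold-standard corpora for biomedical (or any
other) text mining: multiple annotators, multiple rounds, entity and
relation annotation, agreement analysis, and consensus building.

Manually annotated corpora are the substrate on which named-entity
recognition and relation extraction systems are trained and evaluated.
Producing them is iterative: annotators work in rounds, their output is
compared, guidelines are revised, and the cycle repeats until agreement
is acceptable; a final consensus corpus is then adjudicated and exported.
`annokit` implements that whole life cycle as a library plus a thin CLI:

- **Domain model** (`annokit.model`) — immutable documents; typed,
  possibly discontinuous character-span entity mentions (0-based,
  half-open, code-point offsets — the BRAT convention); relations at
  *mention* level (offset-anchored participants) or *document* level
  ((name, type)-anchored, unique per document); annotation provenance
  (annotator, round, manual/recommendation/imported origin); round
  operations: create, copy (hand work to a second annotator), duplicate
  (checkpoint for rollback), finalize.
- **Agreement** (`annokit.agreement`) — inter-annotator agreement (IAA)
  within a round and inter-round agreement (IRA) for one annotator,
  for entities and relations, measured with precision/recall/F over a
  one-to-one matching:

  ```
  precision = |matched| / |A|,   recall = |matched| / |B|,
  F = 2·P·R / (P + R)
  ```

  Matching is *exact* (identical spans) or *relaxed* (spans overlapping
  by at least a user-chosen number of characters). Matched pairs feed a
  per-type agreement matrix whose diagonal gives TP per type, whose row
  remainder (the sum of the horizontal values) gives FP, and whose
  column remainder (the sum of the vertical values) gives FN; the
  off-diagonal cells expose type confusions.
- **Consensus** (`annokit.consensus`) — cluster equivalent annotations
  across annotators, keep clusters supported by at least a threshold
  fraction of annotators (0.5 = "at least half", 1.0 = unanimity), and
  apply manual per-cluster overrides in either direction.
- **Recommendations** (`annokit.recommend`) — project a lexicon
  (harvested from the annotators' own manual history, loaded from a
  two-column dictionary, or imported from an external recognizer) onto
  documents; un-annotated occurrences become recommendations that round
  finalization silently accepts.
- **Simulation** (`annokit.simulate`) — seeded generator of gold corpora
  and imperfect annotators (miss/spurious/jitter/type-flip rates), so
  everything above is testable without external data.
- **I/O** (`annokit.io`) — readers for BRAT standoff, BioNLP standoff,
  BioC inline XML and TSV; deterministic writers for standoff TSV,
  inline TSV, JSON and BioC (plus a BRAT writer).

## Worked example

```python
from annokit import MatchConfig, compute_iaa, prf_from_counts
from annokit.consensus import ConsensusConfig, build_consensus, cluster_annotations
from annokit.simulate import (
    PerturbationParams, build_project, generate_corpus, perturb_annotations,
)

# 1. agreement metrics from a relation contingency triple
m = prf_from_counts(762, 263, 237)
print("precision %d%%  recall %d%%  F %d%%" % m.as_percents())

# 2. a simulated two-annotator round
docs, gold = generate_corpus(
    n_docs=20, entity_types=["Chemical", "Disease"], relation_types=["Effect"],
    mean_entities_per_doc=5, mean_relations_per_doc=1, seed=42)
jane = perturb_annotations(gold, PerturbationParams(drop_prob=0.2, seed=1), "Jane", docs)
john = perturb_annotations(gold, PerturbationParams(drop_prob=0.2, seed=2), "John", docs)
project = build_project("demo", docs, ["Chemical", "Disease"], ["Effect"],
                        ["Jane", "John"], [jane, john])
entities, relations = compute_iaa(project, 1, "Jane", "John", MatchConfig(mode="exact"))
print(f"entity IAA  P={entities.overall.precision:.3f} "
      f"R={entities.overall.recall:.3f} F={entities.overall.f_score:.3f}")
print(f"relation IAA F={relations.overall.f_score:.3f}")

# 3. consensus at the "at least half" threshold
clusters = cluster_annotations([jane, john], MatchConfig(mode="exact"))
final = build_consensus(clusters, ConsensusConfig(threshold=0.5), n_annotators=2, round=1)
print(f"consensus: {len(final.entities)} entities, {len(final.relations)} relations")
```

prints

```
precision 74%  recall 76%  F 75%
entity IAA  P=0.843 R=0.776 F=0.808
relation IAA F=0.720
consensus: 87 entities, 16 relations
```

The triple in step 1 is a relation type with 762 true positives, 263
false positives and 237 false negatives: precision 762/1025 ≈ 0.743,
recall 762/999 ≈ 0.763, F ≈ 0.753, displayed as nearest integer
percents. In step 2 each simulated annotator independently misses 20%
of the gold mentions, so each sees about 80% of what the other marked —
the exact-match P/R land near 0.8 and relations (which require both
endpoints to survive on both sides) agree less. Step 3 keeps every
annotation marked by at least one of the two annotators (support 1 of 2
meets the 0.5 threshold), i.e. the union of the two sets.

The same operations are scriptable from a shell via the `annokit` CLI
(`init`, `import`, `export`, `round new/copy/duplicate/finalize`,
`agreement iaa/ira`, `consensus`, `recommend`, `simulate`); project
state lives in a plain `project.json` per project directory.

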