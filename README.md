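# netreconcile

Attribute-aware reconciliation of literature-derived molecular interaction
lists against curated, signed, directed network models.

Automated readers — rule-based NLP systems and LLM extraction pipelines —
now produce directed, signed molecular interactions far faster than curators
can fold them into mechanistic models. Simply appending them to a curated
network invites redundancy, conflict and implausible structure. This package
is for modellers and knowledge-graph curators who need a *systematic* answer,
per extracted interaction, to the question: does this claim support my model,
conflict with it, extend it, or require a human look?

## The method

Inputs are two BioRECIPE-style tables (tab/comma-delimited or spreadsheet,
one interaction per row): a **baseline graph** — the curated network, held as
a directed multigraph whose nodes are element identities `(identifier,
element type)` — and a **new interaction list**. Each new interaction
`s →± t` is compared against the baseline through formal match conditions:

* **element match**: equal normalized identifier *and* element type;
* **interaction match**: element-matched endpoints plus equal sign;
* **attribute mismatch**: a compared non-essential attribute (compartment,
  mechanism, cell line, cell type, tissue, organism, other context) that is
  non-empty *on both sides* and unequal. Provenance (paper IDs, evidence
  text, reader scores) is never compared.

The decision tree then assigns exactly one category and subcategory:

| category | subcategories | meaning |
|---|---|---|
| corroboration | strong, specification, weak_missing, indirect, path | consistent with a baseline edge or a ≥2-edge shortest path (net sign = parity of negative edges) |
| contradiction | sign, direction, attribute, path | matched elements, conflicting content |
| flagged | direction, path_mismatch, direct_no_edge | ambiguous — deferred to manual inspection |
| extension | full, hanging, internal | absent from the baseline (0, 1 or 2 endpoints known) |

Two configuration axes control strictness. The **attribute-inclusion
strategies** are nested: CA0 = ∅, CA1 = {compartment}, CA2 = CA1 ∪
{mechanism}, CA3 = CA2 ∪ {cell line}, CA4 = CA3 ∪ {remaining context} (or any
custom subset). The **classification schemes** CS1 (default), CS2 and CS3
reinterpret the ambiguous branches: CS1 flags direction-only reversals and
mismatched path alignments; CS2 escalates path mismatches to contradictions
and flags direct claims lacking a direct baseline edge; CS3 inverts the
reversed-edge reading (a pure reversal is a contradiction, a reversal with
additional mismatches is flagged).

Path queries are hop-count shortest-path searches (unit-weight Dijkstra via
networkx) bounded by configurable length and count limits; classification
runs in near-linear time in the list size.

## Worked example

`examples/classify_basics.py` reconciles four extracted claims with a
five-edge AMPK signalling fragment:

```
baseline graph: 5 nodes, 5 edges
LKB1 -> AMPK (direct)              -> corroboration:weak_missing  [edge[0] LKB1 -> AMPK (direct)]
AMPK -| TSC2 (direct)              -> contradiction:sign  [edge[1] AMPK -> TSC2 (direct)]
AMPK -| MTOR (indirect)            -> corroboration:weak_missing  [edge[4] AMPK -| MTOR (indirect)]
FOXO3 -> SOD2 (direct)             -> extension:full
```

The first claim duplicates a baseline edge (weak corroboration: the compared
compartments are empty on both sides, so the match carries no attribute
evidence); the second hits the same edge with the opposite sign
(contradiction); the third matches a known indirect inhibition; the fourth
involves two unknown proteins and is a candidate model extension. The other
examples (`scheme_comparison.py`, `attribute_strategies.py`,
`synthetic_benchmark.py`) walk the scheme semantics, the CA0→CA4 sweep, and
the planted-truth benchmark generator.

The same pipeline is available from the shell:

```bash
netreconcile fixtures --seed 3 --out-dir fx
netreconcile reconcile --baseline fx/baseline.tsv --interactions fx/new_interactions.tsv \
    --scheme CS1 --attributes CA1 --out classified.tsv --summary summary.tsv
netreconcile summarize --classified classified.tsv --baseline fx/baseline.tsv
```

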