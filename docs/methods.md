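# Methods

## Problem setting

A curated mechanistic model is a directed, signed, attributed interaction
graph: nodes are biological elements (proteins, genes, RNAs, chemicals,
processes), edges carry a regulatory sign (positive/negative), a connection
type (direct single-step vs indirect multi-step regulation) and optional
contextual attributes. Automated readers emit candidate interactions in the
same tabular dialect. Reconciliation decides, for each candidate, how it
relates to the curated graph. The package implements this as a deterministic
decision procedure over formal match conditions, with the semantics of
ambiguous cases (reversed edges, path-level alignment, unsupported direct
claims) exposed as configuration rather than hard-coded policy.

## Identity and normalization

Element identity is the pair (identifier, element type). Identifiers are
trimmed and lower-cased (idempotent); an element with several identity
columns populated uses database ID over gene symbol over free-text name, and
records which was used. Unknown element types map to `other`. Sign and
connection values are mapped through explicit, editable vocabularies
(`activation`/`+`/`increase` → positive, etc.); unmappable values are
row-indexed parse errors, never guessed. A missing connection type defaults
to *indirect* — the conservative choice, since the stricter decision
branches (CS2's `direct_no_edge` flag) apply only to direct claims, and
unannotated rows should not trigger them. Attribute values are compared
after lower-casing and trimming with no synonym resolution: entity and
attribute grounding is the responsibility of the upstream extraction
pipeline, and grounding errors surface here as spurious extensions rather
than being silently papered over.

## Graph store and path search

The baseline is a `networkx.MultiDiGraph` keyed by element identity; every
input row becomes exactly one edge, so parallel edges with different sign or
attributes coexist. A collapsed unit-weight `DiGraph` supports shortest-path
queries by hop count (equivalent to Dijkstra with unit weights). A *path* is
a chain of ≥ 2 edges: a direct baseline edge is never a path, so the search
excludes the collapsed (s, t) edge before enumerating. All minimum-length
node sequences are enumerated, ordered lexicographically by node key, and
expanded over parallel edges in baseline row order; the search stops at
`max_path_len` hops (default 6) and `max_paths` paths (default 10). The
defaults bound the worst case on dense graphs — path search dominates the
cost of classification — while being far beyond the 2–3 hop alignments that
occur in practice; both are configurable.

A path's **net sign** is positive iff it contains an even number of negative
edges — standard signed-network composition. Because the composition rule is
a modelling choice, a `sign_mode` switch selects between this multiplicative
parity (default, `net`) and a strict mode in which every edge on the path
must carry the new interaction's sign.

## Match conditions

Two elements match iff identifier and type are both equal. The necessary
interaction match is element-matched endpoints plus equal sign; a sign
conflict between matched endpoints is a *contradiction*, not a non-match.
Attribute mismatches are computed only over the attributes selected by the
inclusion strategy, and a pair with at least one empty side never counts as
a mismatch (the empty-exclusion rule; for the `context_other` map it is
applied key by key, ignoring keys present on one side only). Compartment is
an element-level attribute and is compared per matched endpoint —
source-vs-source and target-vs-target, crosswise when the comparison pairs a
reversed edge or reversed path. For path comparisons, scalar attributes are
aggregated as the union of per-edge conflicts, while compartments are
compared at the path termini only, since intermediate nodes have no
counterpart on the new interaction. Provenance fields are structurally
excluded: the strategy type refuses to include them, and the comparison code
never reads them.

## The decision tree

Deterministic order, first match wins:

1. **Membership.** Neither endpoint known → extension *full*; exactly one →
   extension *hanging*.
2. **Forward edge.** Among parallel edges, the best match is the one with
   the fewest mismatches (sign weighted heaviest, then attribute count, then
   connection disagreement; ties broken by baseline row order) — this
   prevents a sign-consistent parallel edge from being shadowed by a
   conflicting one. Sign mismatch → contradiction *sign* (dominates
   attribute conflicts in the subcategory label; the full mismatch set is
   retained in the output). Attribute mismatch → contradiction *attribute*.
   Otherwise corroboration, with subtype precedence: *indirect* if the
   connection types differ; *strong* if every compared attribute slot is
   non-empty and equal on both sides (vacuously true under CA0);
   *specification* if the new interaction fills ≥ 1 attribute the baseline
   leaves empty and loses none; *weak_missing* otherwise (baseline-only or
   both-empty values).
3. **Reversed edge.** The mismatch set is {direction} plus any sign or
   attribute conflicts against the best reversed edge (compartments paired
   crosswise). Connection-type disagreement does *not* enlarge the set: an
   indirect report of a direct reversed edge is still a direction-only case.
   CS1/CS2: direction-only → flagged, anything more → contradiction. CS3
   inverts this reading.
4. **Path.** Forward shortest paths are tried first, then reversed ones.
   For an indirect claim: if at least one enumerated forward path is fully
   consistent (net sign agrees, no attribute conflicts) → corroboration
   *path*; otherwise the least-mismatched path is reported and the case is
   flagged *path_mismatch* (CS1/CS3) or contradiction *path* (CS2). A direct
   claim that merely aligns with a path is an extension *internal* (CS1/CS3)
   or flagged *direct_no_edge* (CS2).
5. **No connection.** Both nodes known, no edge or path either way:
   extension *internal*, except that CS2 flags direct claims as
   *direct_no_edge*. CS2's flag is applied with or without a connecting path
   (the stricter, more consistent reading); a config switch
   (`cs2_flag_unconnected_direct=False`) restricts it to path-aligned claims.

Self-loops use only steps 1–2; an unmatched self-loop between a known node
and itself is an extension *internal* under every scheme, since the
scheme-specific rules all live in the skipped steps.

Precedence across steps — forward edge over reversed edge, edges over paths,
forward paths over reversed paths — is the most-specific-match-first
ordering. The scheme definitions for reversed edges (step 3) are applied to
both direct and indirect claims; this is the reading under which all five
built-in scheme-comparison scenarios (see `netreconcile/demo.py`) come out
with their documented labels.

## Reporting

`summarize` produces category/subcategory counts and fractions plus baseline
coverage: a baseline edge is corroborated (contradicted) if at least one
classified interaction of that category matched it. Path-mediated matches
mark every edge on the matched path by default — path corroborations are
typically the dominant corroboration subtype, so ignoring them would hide
most verified structure — and `path_coverage=False` restricts coverage to
directly matched edges. Percentages are reported to 0.1%.

## Synthetic benchmark generator

`fixtures.generate` emulates the structure of a reconciliation workload: a
directed Erdős–Rényi background graph (default 30 nodes / 60 edges, 80%
positive edges — curated signalling networks are activation-heavy — with
contextual attributes filled at rate 0.7), plus one dedicated sub-structure
per planted decision-tree leaf. Plants own their nodes (background and plant
namespaces are disjoint), so each plant's label under every scheme ×
strategy combination is derivable at generation time and recorded in the
truth table; infeasible plant requests raise a generation error naming the
leaf. A duplicate rate appends repeated rows for deduplication tests. All
randomness flows from a single seeded RNG; identical spec + seed yields
byte-identical files.

What the generator does *not* emulate: grounding noise (identifier synonymy,
type confusion), attribute vocabulary drift, belief scores, and the skewed
category distributions of real reader output (real lists are dominated by
extensions; fixtures are balanced across leaves by design). Passing the
closure tests therefore demonstrates decision-tree correctness, not
robustness to upstream extraction error.

`brute_force_classify` is an independent oracle with the same contract:
linear scans over baseline rows and exhaustive DFS path enumeration, no code
shared with the production classifier, refusing graphs above 12 nodes. The
configured path limits (`max_len`, `max_paths`, deterministic ordering) are
part of the contract and are honoured by both implementations.

## Numerical and tie-breaking choices

All comparisons are exact string equality after normalization; there are no
floating-point tolerances in the classifier. Every ordering ambiguity is
resolved deterministically: parallel edges by baseline row order, equal-length
paths lexicographically by node key, parallel-edge expansion in row order.
Same inputs and configuration always produce byte-identical outputs.

## Problem sizes used in the checks

The acceptance battery runs at desk scale: 600 randomized oracle-equivalence
instances (graphs of 3–10 nodes), generator closure over 3 plants per leaf ×
15 configurations, five fixture replicates for the monotonicity check, and a
runtime sweep at list sizes 100 / 1000 / 10000 against a fixed 40-node
baseline (fitting wall time vs size linearly; R² > 0.95 is the pass bar, and
observed per-interaction cost is ~0.01 ms on this path-light mixture).
Checks against the two externally published curated baseline graphs and the
831-interaction expert-labeled benchmark require files that are not
redistributed with the package (`data/external/README.md`); the
corresponding tests fail with a download pointer when the files are absent.

## Known limitations

* No fuzzy or ontology-aware attribute equivalence (cell-line synonyms,
  compartment hierarchies); equal means string-equal.
* Reconciliation is pairwise and structural; reader belief scores are
  carried as provenance but never weighted into decisions.
* Path search is bounded; on graphs where the only consistent alignment is
  longer than `max_path_len` hops (or beyond `max_paths` enumerations) an
  indirect claim degrades to a path mismatch or internal extension.
* "Specification" covers attribute refinement only, not element-subtype
  refinement.
* Extensions are reported as candidates; merging them into the baseline
  model is downstream work and out of scope.
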