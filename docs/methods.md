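# Methods

## Integration by notation

The toolkit merges terminology sets purely by term notation: two occurrences
of the same string are the same term. This is the assumption under which the
original vocabularies were meant to be combined, and it is also what makes
the audit meaningful — every inconsistency the checks report is a place where
that assumption breaks (the same spelling is used for different things, or
different spellings for the same thing).

Normalization is therefore deliberately minimal: Unicode canonical
composition (NFC) plus stripping of leading/trailing whitespace, including
the ideographic space U+3000. Width, case and punctuation are preserved,
because near-identical strings are themselves findings: definitions that
differ only by a trailing "。", or CDRH-NCIt mappings that differ only in
capitalization ("Material deformation" vs "material deformation"), must be
counted as distinct for the multi-definition and multi-mapping checks to
report them. Optional `width_fold` (NFKC) and `case_fold` flags exist for
vocabularies known to mix widths or cases, and the multi-mapping check has a
`case_insensitive` mode; all default off. `normalize_label` is idempotent and
rejects labels that normalize to the empty string.

## Graph model

One graph per problem domain. Device-problem and patient-problem graphs are
never merged, because the same notation may legitimately sit at different
hierarchy levels in the two domains and a merge would silently exchange those
hierarchies; sharing across domains is instead detected by the cross-domain
check over the pair of graphs.

Nodes are labels with role sets ⊆ {category, preferred, synonym}; the role
set accumulates every position the label occupies across all input sets, so a
label used at both hierarchy levels keeps a single node with both roles.
Edges are distinct (subject, object) pairs per relation; a relation asserted
by several terminology sets becomes one edge whose provenance is the set of
terminology IDs. Provenance is retained because remediation is addressed to
the associations that disagree — every finding names the sets supporting it.
Definitions and CDRH-NCIt terms are literal objects, not nodes: the checks
only need per-preferred-term multisets of strings. Self-edges (a record whose
category and preferred label coincide) are retained; they surface as
1-cycles and identical-label dual-role findings.

Counting conventions: the "combined" term count is the number of distinct
labels holding the category or preferred role (synonym-only labels are
alternative notations, not hierarchy members). Pre-integration tallies are
reconstructed per terminology ID from edge provenance and summed, so the
duplicate-removal percentage is 100 × (1 − post/pre) on combined counts.

## Pattern semantics of the structural checks

For the dual-role and swap checks a *pattern* is one concrete context
evidencing the inconsistency — the row a structural query over the graph
would return — and the unique-term count collapses patterns to distinct
flagged labels. For a dual-role term the contexts are the cross product of
its category parents and its preferred children, which is why pattern counts
can exceed unique-term counts by an order of magnitude on real data. This
cross-product reading is the natural mechanical interpretation of a
three-variable hierarchy query; since other row semantics are conceivable,
pattern counts should be read as tied to this definition, while unique-term
counts and multiplicities are definition-independent. The swap check reports
the flagged-term count as `unique_term_count` and additionally
`alt_unique_term_count` over all labels appearing in any pattern, since
either tally is a defensible "number of exchanged terms".

Cycle detection enumerates all elementary cycles of the directed subclass
relation (networkx's algorithm; an independent exhaustive DFS serves as the
test oracle), reporting each cycle once in its lexicographically smallest
rotation. 1-cycles are identical-label records; 2-cycles are hypernym/hyponym
inversions between terminology sets.

All checks are pure functions of their input graphs, and findings are sorted
lexicographically by pattern, so repeated runs — and therefore reports — are
byte-identical.

## RDF interchange

The Turtle/N-Triples export exists for interoperability (loading the
integrated terminology into a SPARQL engine or ontology editor), not as the
computation engine — the checks are native graph operations. Since label
identity is the merge key, a term's IRI is a pure function of its label: the
percent-encoded label under a per-domain namespace. Hierarchy edges use
`rdfs:subClassOf`, definitions `rdfs:isDefinedBy`, synonym and CDRH-NCIt
edges project-namespace predicates. Edge provenance travels through standard
RDF reification with skolem statement IRIs derived from a SHA-1 of the
triple, avoiding blank-node nondeterminism; triples are emitted in sorted
order so serialization is deterministic, and import→export is the identity
on graphs.

## Synthetic data

The generator emulates the *shape* of the real release: 89 sets by default,
both problem domains, ~11 categories per set and domain with ~3 preferred
terms each (≈ 3,400 preferred-term rows per domain before integration,
matching the published scale), one synonym, one definition and one CDRH-NCIt
mapping per preferred term. Whole records are shared across sets through a
global template pool sized by `duplication_factor` (default 2.5), which
reproduces the observed ~60% duplicate removal on integration. It does **not**
emulate real label-frequency distributions, real Japanese vocabulary, or the
correlated, messy way real associations disagree: labels are opaque tokens
from pools disjoint per purpose. Passing tests therefore demonstrate that the
machinery counts exactly what it defines — not that real data contains any
particular number of inconsistencies.

Planted inconsistencies are minimal record pairs from dedicated disjoint
pools, one structure per check, so expected counts are exact. The one
structural overlap is unavoidable: a planted cycle of length L makes each of
its labels both a category and a preferred term, adding exactly L dual-role
patterns; the bookkeeping accounts for this explicitly. Generation is a pure
function of the config (seed included); infeasible configs (multiplicities
< 2, negative counts, cycle length 0) are rejected up front.

## Numerical and design choices

- **Tie-breaks / ordering:** findings sort lexicographically by pattern
  (None sorts first); report listings sort by multiplicity descending, then
  label code point; JSON reports use sorted keys — all to make outputs
  diffable and maxima stable.
- **Percent denominators:** per-check percentages divide unique flagged terms
  by the post-integration combined term count of the same domain; the report
  states this in-band, since percentage denominators are otherwise a common
  source of irreproducibility.
- **Degenerate inputs:** empty inputs yield empty graphs, all-zero reports
  with a `degenerate_input` flag, and reduction/percentages reported as 0
  rather than NaN.
- **Ingest strictness:** missing required columns, unparseable domain values
  and empty category/preferred cells are hard errors with row numbers;
  duplicate rows, self-synonyms and blank definitions are collected by the
  validator (never raised), because detecting them in published data is part
  of the audit. Records from the other domain are skipped with a logged
  count when building a graph.
- **Dialects:** the original spreadsheets' intra-cell list convention is not
  standardized, so the synonym/CDRH-NCIt cell delimiter (default comma with
  CSV-style double-quote escaping, preserving items like
  "Vessels, perforation of"), the column delimiter and the header-name
  mapping (Japanese and English accepted out of the box) are all
  configurable via a YAML dialect file.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
worked-example fixtures are a few hundred records; the brute-force oracle
comparisons use random graphs of ≤ 50 nodes, where exhaustive enumeration is
trivially correct; planted-recovery runs 200 randomized small configurations;
and the full-shape synthetic release is ~6,000 records, the same order as the
real release. Everything completes in seconds on one CPU.

## Known limitations

- Pattern counts for the dual-role and swap checks depend on the
  cross-product row semantics above; alternative query formulations would
  give different pattern tallies over the same inconsistent terms.
- The tool detects and lists; it makes no judgment about which hierarchy
  level, definition or mapping is correct, and proposes no repairs.
- Semantic classification of why a hierarchy is inconsistent (schema-vs-detail
  vs cause-effect relations) requires reading the terms' meanings and is out
  of scope, as is any multilingual mapping improvement (edit distance,
  embeddings) for the CDRH-NCIt correspondences.
- Only the seven-column first-edition layout is supported; later editions
  with four term categories and IMDRF codes are not.
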