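# termaudit

Integrate many independently authored two-level adverse-event terminologies
into one labeled graph per problem domain, and audit the result for
structural inconsistencies.

## The problem

Adverse events involving medical devices are reported with controlled
vocabularies. The Japanese first-edition release comprises 89 per-device-group
terminology sets, written bottom-up by 13 different industry associations.
Each set has two sections — *medical device problems* and *patient problems* —
and a two-level hierarchy in each: upper-level **category terms** group
lower-level **preferred terms**; a preferred term carries **synonyms**, a
free-text **definition**, and mappings to the **CDRH-NCIt** terminology.

Because the sets were authored independently, merging them by term notation
(same spelling ⇒ same term) exposes disagreements: a label used as a category
term in one set and a preferred term in another silently creates three-level
chains; preferred terms and synonyms get exchanged; one preferred term ends up
under many category parents, or with many competing definitions or CDRH-NCIt
mappings; hypernym/hyponym pairs get inverted into cycles; and the same label
serves both problem domains. `termaudit` performs the integration and detects
all of these mechanically, so that terminology maintainers — not the tool —
can decide what to fix.

## The model

Each problem domain gets its own integrated graph (the two are never merged:
cross-domain reuse is itself one of the audit checks). Nodes are normalized
labels (Unicode NFC + trim; width, case and punctuation preserved), each
carrying the set of roles it occupies anywhere: `category`, `preferred`,
`synonym`. Edges follow a fixed relation schema with the terminology IDs that
assert them kept as provenance:

| relation | meaning |
| --- | --- |
| `rdfs:subClassOf` | preferred term → its category term |
| `hasSynonym` | preferred term → synonym |
| `correspondenceOf` | preferred term → CDRH-NCIt term |
| `rdfs:isDefinedBy` | preferred term → definition string |

Seven audit operations run over the graph(s): (1) dual-role labels, with one
*pattern* per (parent, term, child) context; (2) preferred/synonym swaps;
(3) polyhierarchy (≥ 2 category parents); (4) multiple distinct definitions;
(5) multiple CDRH-NCIt mappings; (6) labels used as hierarchy terms in both
domains; plus enumeration of all elementary cycles in the subclass relation
(1-cycles = identical label at both levels, 2-cycles = inverted hierarchies).
Each check reports patterns, unique flagged terms, and — for the multiplicity
checks — the largest multiplicity and the top offenders.

## Worked example

```bash
python examples/audit_worked_examples.py
```

prints, from the bundled worked-example fixtures:

```
max category parents of one preferred term: 11
  worst offender: 変形 under 11 categories
distinct definitions of 感染: 8
  (two of them differ only by a trailing 。 — exact-string distinctness)
distinct CDRH-NCIt mappings of 穿孔: 4
labels used as hierarchy terms in BOTH domains: 8
  その他, その他の事象, 不明, 感染, 感電, 損傷, 汚染, 発熱
```

That is: the worst polyhierarchy case is 変形 (deformation), filed under 11
different category terms; 感染 (infection) carries 8 competing definition
strings — two differing only by a trailing full stop, which the audit
deliberately counts as distinct; 穿孔 (perforation) maps to 4 different
CDRH-NCIt terms; and 8 labels (損傷, 感染, …) are used as hierarchy terms in
both the device-problem and the patient-problem vocabulary.

`examples/synthetic_release_audit.py` generates a full-shape synthetic
release (89 sets, both domains, records shared across sets) with planted
inconsistencies and shows the integration removing ~61–63% duplicate terms
while every check returns exactly the planted counts.
`examples/rdf_export_roundtrip.py` shows the deterministic Turtle export and
the lossless re-import.

## Command line

The same pipeline is scriptable from a shell:

```bash
termaudit synth --seed 1 --out synth/                      # synthetic release + bookkeeping
termaudit ingest synth/terminologies.csv --out norm.csv    # validate + normalize
termaudit audit synth/terminologies.csv --out report/      # report.json + findings.jsonl
termaudit export-rdf synth/terminologies.csv --domain device --out device.ttl
```

`audit` exits 0 even when findings exist (findings are data, not failures);
pass `--fail-on-findings` to gate a CI job. Input dialects (TSV, alternative
intra-cell delimiters, Japanese or English headers) are configured with a
small YAML file passed via `--dialect`.

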