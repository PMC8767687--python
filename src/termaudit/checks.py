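"""Structural inconsistency checks over integrated terminology graphs.

Six audit checks, mirroring the questions a terminology editor asks of a
merged two-level vocabulary, plus hierarchy-cycle detection:

1. dual-role — is any label used as a category term in one terminology and
   a preferred term in another? Merging such sets by notation silently
   creates three-or-more-level chains.
2. preferred/synonym swap — do two terminologies disagree about which of a
   pair is the preferred term and which the synonym?
3. multi-parent — is a preferred term subordinate to two or more distinct
   category terms (polyhierarchy)?
4. multi-definition — does a preferred term carry two or more distinct
   definition strings?
5. multi-mapping — does a preferred term map to two or more distinct
   CDRH-NCIt terms?
6. cross-domain — is the same label used as a hierarchy term in both the
   device-problem and the patient-problem vocabulary?

A *pattern* is one concrete context evidencing an inconsistency (one row a
structural query would return); the *unique term count* collapses patterns
to distinct flagged labels. For checks 1–2 a flagged term's patterns are
the cross product of its left and right neighbours, so pattern counts can
far exceed unique-term counts.

All checks are pure functions: they never mutate the graph and repeated
runs return identical results, with findings in lexicographic pattern
order.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

import networkx as nx

from .graph import (
    CATEGORY,
    CORRESPONDENCE,
    DEFINITION,
    PREFERRED,
    SUBCLASS,
    SYNONYM,
    IntegratedGraph,
)

DUAL_ROLE = 1
SWAP = 2
MULTI_PARENT = 3
MULTI_DEFINITION = 4
MULTI_MAPPING = 5
CROSS_DOMAIN = 6
CYCLE = "cycle"


@dataclass(frozen=True)
class Finding:
    """One detected inconsistency.

    ``pattern`` is the context tuple (arity depends on the check; nested
    tuples hold sorted multiplicities); ``involved_terms`` are the labels
    judged inconsistent; ``provenance`` names the terminology sets whose
    assertions support the pattern — the audit's output is addressed to
    them. ``flags`` carries sub-classifications (currently only
    "identical-label": a single record used the same string at both
    hierarchy levels).
    """

    check_id: int | str
    pattern: tuple
    involved_terms: frozenset[str]
    provenance: frozenset[str]
    flags: frozenset[str] = frozenset()


@dataclass
class CheckResult:
    """Outcome of one check on one graph (or graph pair for cross-domain)."""

    check_id: int | str
    findings: list[Finding] = field(default_factory=list)
    pattern_count: int = 0
    unique_term_count: int = 0
    max_multiplicity: int | None = None
    #: checks with ambiguous unique-count semantics also report the count
    #: over all labels appearing in any pattern (flagged terms ∪ partners)
    alt_unique_term_count: int | None = None


def _sort_key(pattern: tuple):
    return tuple("" if x is None else (x if isinstance(x, tuple) else (x,)) or ("",)
                 for x in pattern)


def _finish(check_id, findings: list[Finding], unique_terms: set[str],
            max_multiplicity: int | None = None,
            alt_unique: int | None = None) -> CheckResult:
    findings = sorted(findings, key=lambda f: _sort_key(f.pattern))
    return CheckResult(
        check_id=check_id,
        findings=findings,
        pattern_count=len(findings),
        unique_term_count=len(unique_terms),
        max_multiplicity=max_multiplicity,
        alt_unique_term_count=alt_unique,
    )


def check_dual_role(graph: IntegratedGraph) -> CheckResult:
    """Check 1: labels present at both hierarchy levels.

    A term T with both category and preferred roles yields one pattern per
    distinct (parent, T, child) triple, where (T subClassOf parent) and
    (child subClassOf T); self-edges are allowed, so parent or child may
    equal T. A record whose category and preferred labels are the same
    string additionally carries the "identical-label" flag.
    """
    sub = graph.edges[SUBCLASS]
    parents_of: dict[str, list[str]] = {}
    children_of: dict[str, list[str]] = {}
    for (child, parent) in sub:
        parents_of.setdefault(child, []).append(parent)
        children_of.setdefault(parent, []).append(child)

    findings: list[Finding] = []
    unique: set[str] = set()
    for term, roles in graph.nodes.items():
        if not roles >= {CATEGORY, PREFERRED}:
            continue
        unique.add(term)
        has_self = (term, term) in sub
        for parent in parents_of.get(term, ()):
            for child in children_of.get(term, ()):
                prov = sub[(term, parent)] | sub[(child, term)]
                flags = set()
                if has_self and (parent == term or child == term):
                    flags.add("identical-label")
                findings.append(
                    Finding(
                        check_id=DUAL_ROLE,
                        pattern=(parent, term, child),
                        involved_terms=frozenset({term}),
                        provenance=frozenset(prov),
                        flags=frozenset(flags),
                    )
                )
    return _finish(DUAL_ROLE, findings, unique)


def check_preferred_synonym_swap(graph: IntegratedGraph) -> CheckResult:
    """Check 2: labels that are a synonym in one set, a preferred term in another.

    X is flagged iff some preferred term P lists X as a synonym while X
    itself occupies the preferred role anywhere. One pattern per distinct
    (P, X, S) with (P hasSynonym X) and (X hasSynonym S); when the
    flagged X has no synonyms of its own the pattern is (P, X, None).
    """
    syn = graph.edges[SYNONYM]
    syns_of: dict[str, list[str]] = {}
    for (pref, s) in syn:
        syns_of.setdefault(pref, []).append(s)

    findings: list[Finding] = []
    unique: set[str] = set()
    partners: set[str] = set()
    for (pref, x) in syn:
        if PREFERRED not in graph.roles(x):
            continue
        unique.add(x)
        partners.add(pref)
        own = syns_of.get(x)
        if own:
            for s in own:
                partners.add(s)
                findings.append(
                    Finding(
                        check_id=SWAP,
                        pattern=(pref, x, s),
                        involved_terms=frozenset({x}),
                        provenance=frozenset(syn[(pref, x)] | syn[(x, s)]),
                    )
                )
        else:
            findings.append(
                Finding(
                    check_id=SWAP,
                    pattern=(pref, x, None),
                    involved_terms=frozenset({x}),
                    provenance=frozenset(syn[(pref, x)]),
                )
            )
    return _finish(SWAP, findings, unique, alt_unique=len(unique | partners))


def _multiplicity_check(
    check_id: int,
    pairs: dict[tuple[str, str], set[str]],
    keys: dict[str, list[str]],
) -> CheckResult:
    findings: list[Finding] = []
    unique: set[str] = set()
    max_mult: int | None = None
    for subject, objects in keys.items():
        distinct = sorted(set(objects))
        if len(distinct) < 2:
            continue
        unique.add(subject)
        prov: set[str] = set()
        for obj in objects:
            prov |= pairs[(subject, obj)]
        findings.append(
            Finding(
                check_id=check_id,
                pattern=(subject, tuple(distinct)),
                involved_terms=frozenset({subject}),
                provenance=frozenset(prov),
            )
        )
        max_mult = max(max_mult or 0, len(distinct))
    return _finish(check_id, findings, unique, max_multiplicity=max_mult)


def check_multi_parent(graph: IntegratedGraph) -> CheckResult:
    """Check 3: preferred terms subordinate to two or more category terms.

    Pattern = (preferred, sorted parent tuple); a self-parent counts.
    max_multiplicity is the largest parent-set size found.
    """
    sub = graph.edges[SUBCLASS]
    parents: dict[str, list[str]] = {}
    for (child, parent) in sub:
        parents.setdefault(child, []).append(parent)
    return _multiplicity_check(MULTI_PARENT, sub, parents)


def check_multi_definition(graph: IntegratedGraph) -> CheckResult:
    """Check 4: preferred terms with two or more distinct definition strings.

    Distinctness is exact-string after NFC + trim: trailing punctuation is
    significant, so two definitions differing only by a final "。" count
    separately — near-duplicate definitions are themselves a finding.
    """
    defs = graph.edges[DEFINITION]
    by_subject: dict[str, list[str]] = {}
    for (subject, text) in defs:
        by_subject.setdefault(subject, []).append(text)
    return _multiplicity_check(MULTI_DEFINITION, defs, by_subject)


def check_multi_mapping(
    graph: IntegratedGraph, *, case_insensitive: bool = False
) -> CheckResult:
    """Check 5: preferred terms mapped to two or more CDRH-NCIt terms.

    Comparison defaults to case-sensitive exact match after trim;
    ``case_insensitive=True`` folds case first (published mappings mix
    capitalizations of the same English term).
    """
    corr = graph.edges[CORRESPONDENCE]
    by_subject: dict[str, list[str]] = {}
    if case_insensitive:
        folded_pairs: dict[tuple[str, str], set[str]] = {}
        for (subject, target), prov in sorted(corr.items()):
            folded_pairs.setdefault((subject, target.casefold()), set()).update(prov)
            by_subject.setdefault(subject, []).append(target.casefold())
        return _multiplicity_check(MULTI_MAPPING, folded_pairs, by_subject)
    for (subject, target) in corr:
        by_subject.setdefault(subject, []).append(target)
    return _multiplicity_check(MULTI_MAPPING, corr, by_subject)


def _hierarchy_provenance(graph: IntegratedGraph, label: str) -> set[str]:
    prov: set[str] = set()
    for (child, parent), p in graph.edges[SUBCLASS].items():
        if label in (child, parent):
            prov |= p
    return prov


def check_cross_domain(
    device_graph: IntegratedGraph, patient_graph: IntegratedGraph
) -> CheckResult:
    """Check 6: hierarchy labels shared between the two problem domains.

    Flags every label holding the category or preferred role in BOTH
    graphs; labels that are synonym-only in one domain are not flagged.
    Pattern = (label, roles in device graph, roles in patient graph).
    """
    findings: list[Finding] = []
    unique: set[str] = set()
    hierarchy = {CATEGORY, PREFERRED}
    for label, droles in device_graph.nodes.items():
        if not droles & hierarchy:
            continue
        proles = patient_graph.roles(label)
        if not proles & hierarchy:
            continue
        unique.add(label)
        prov = _hierarchy_provenance(device_graph, label) | _hierarchy_provenance(
            patient_graph, label
        )
        findings.append(
            Finding(
                check_id=CROSS_DOMAIN,
                pattern=(label, tuple(sorted(droles)), tuple(sorted(proles))),
                involved_terms=frozenset({label}),
                provenance=frozenset(prov),
            )
        )
    return _finish(CROSS_DOMAIN, findings, unique)


def _canonical_rotation(cycle: list[str]) -> tuple[str, ...]:
    i = cycle.index(min(cycle))
    return tuple(cycle[i:] + cycle[:i])


def detect_hierarchy_cycles(graph: IntegratedGraph) -> list[tuple[str, ...]]:
    """All elementary cycles in the directed subclass relation.

    Includes 1-cycles (a record with the same label at both levels) and
    2-cycles (two terminologies listing each other's hypernym/hyponym
    inverted). Each cycle is reported once, rotated to start at its
    lexicographically smallest label; edges point child → parent.
    """
    dg = nx.DiGraph()
    dg.add_edges_from(graph.edges[SUBCLASS].keys())
    cycles = [_canonical_rotation(c) for c in nx.simple_cycles(dg)]
    return sorted(cycles, key=lambda c: (len(c), c))


def cycles_as_result(graph: IntegratedGraph) -> CheckResult:
    """Wrap detect_hierarchy_cycles in the common CheckResult shape."""
    sub = graph.edges[SUBCLASS]
    findings = []
    for cyc in detect_hierarchy_cycles(graph):
        prov: set[str] = set()
        for i, child in enumerate(cyc):
            parent = cyc[(i + 1) % len(cyc)]
            prov |= sub[(child, parent)]
        findings.append(
            Finding(
                check_id=CYCLE,
                pattern=cyc,
                involved_terms=frozenset(cyc),
                provenance=frozenset(prov),
            )
        )
    unique = {label for f in findings for label in f.involved_terms}
    return _finish(CYCLE, findings, unique)


def run_all_checks(
    device_graph: IntegratedGraph, patient_graph: IntegratedGraph
) -> dict:
    """Run checks 1–5 per domain, check 6 across, cycles per domain.

    Returns {check_id: {"device": CheckResult, "patient": CheckResult}}
    for per-domain checks and {6: CheckResult} for the cross-domain one.
    """
    per_domain = {
        DUAL_ROLE: check_dual_role,
        SWAP: check_preferred_synonym_swap,
        MULTI_PARENT: check_multi_parent,
        MULTI_DEFINITION: check_multi_definition,
        MULTI_MAPPING: check_multi_mapping,
        CYCLE: cycles_as_result,
    }
    results: dict = {}
    for cid, fn in per_domain.items():
        results[cid] = {
            "device": fn(device_graph),
            "patient": fn(patient_graph),
        }
    results[CROSS_DOMAIN] = check_cross_domain(device_graph, patient_graph)
    return results


def _pattern_to_json(pattern: tuple):
    return [list(x) if isinstance(x, tuple) else x for x in pattern]


def _pattern_to_text(pattern: tuple) -> str:
    parts = []
    for x in pattern:
        if isinstance(x, tuple):
            parts.append(" | ".join(x))
        elif x is None:
            parts.append("")
        else:
            parts.append(x)
    return " ;; ".join(parts)


def findings_to_jsonl(findings: list[Finding]) -> str:
    """One JSON object per finding, stable key order."""
    lines = []
    for f in findings:
        lines.append(
            json.dumps(
                {
                    "check_id": f.check_id,
                    "pattern": _pattern_to_json(f.pattern),
                    "involved_terms": sorted(f.involved_terms),
                    "provenance": sorted(f.provenance),
                    "flags": sorted(f.flags),
                },
                ensure_ascii=False,
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def findings_to_csv(findings: list[Finding]) -> str:
    """One CSV row per pattern: check_id, pattern, terms, provenance, flags."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["check_id", "pattern", "involved_terms", "provenance", "flags"])
    for f in findings:
        writer.writerow(
            [
                f.check_id,
                _pattern_to_text(f.pattern),
                " | ".join(sorted(f.involved_terms)),
                " | ".join(sorted(f.provenance)),
                " | ".join(sorted(f.flags)),
            ]
        )
    return buf.getvalue()
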