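"""The integrated per-domain terminology graph.

Integration merges terms purely by notation: every distinct normalized
label becomes one node, and relations contributed by different terminology
sets collapse onto one edge whose provenance records which sets assert it.
Device-problem and patient-problem graphs are built separately and never
merged — the same notation may sit at different hierarchy levels in the two
domains, and merging would silently exchange those hierarchies; the
cross-domain audit check compares the two graphs instead.

Relations follow the published schema: ``subClassOf`` links a preferred
term up to its category term, ``hasSynonym`` links a preferred term to a
synonym, ``correspondenceOf`` links a preferred term to a CDRH-NCIt term,
and ``isDefinedBy`` attaches a definition string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import ProblemDomain, TerminologySet

logger = logging.getLogger(__name__)

SUBCLASS = "subClassOf"
SYNONYM = "hasSynonym"
CORRESPONDENCE = "correspondenceOf"
DEFINITION = "isDefinedBy"

PREDICATES = (SUBCLASS, SYNONYM, CORRESPONDENCE, DEFINITION)

#: node roles
CATEGORY = "category"
PREFERRED = "preferred"
SYNONYM_ROLE = "synonym"


@dataclass
class IntegratedGraph:
    """Per-domain merged graph of labels and provenance-tagged relations.

    ``nodes`` maps each term label to the set of roles it occupies anywhere
    across the input sets (subset of {category, preferred, synonym}); a
    label used as both a category and a preferred term keeps a single node
    carrying both roles, which is exactly what the dual-role audit check
    looks for. Each ``edges[predicate]`` maps a (subject, object) pair to
    the non-empty set of terminology IDs asserting it. For ``subClassOf``
    the pair is (child=preferred, parent=category); self-edges (a record
    whose category and preferred term are the same string) are retained.
    Objects of ``correspondenceOf``/``isDefinedBy`` are literals, not nodes.
    """

    problem_domain: ProblemDomain
    nodes: dict[str, set[str]] = field(default_factory=dict)
    edges: dict[str, dict[tuple[str, str], set[str]]] = field(
        default_factory=lambda: {p: {} for p in PREDICATES}
    )

    def _add_role(self, label: str, role: str) -> None:
        self.nodes.setdefault(label, set()).add(role)

    def add_edge(self, predicate: str, subject: str, obj: str, provenance: str) -> None:
        if predicate not in self.edges:
            raise ValueError(f"unknown predicate: {predicate!r}")
        self.edges[predicate].setdefault((subject, obj), set()).add(provenance)
        if predicate == SUBCLASS:
            self._add_role(subject, PREFERRED)
            self._add_role(obj, CATEGORY)
        elif predicate == SYNONYM:
            self._add_role(subject, PREFERRED)
            self._add_role(obj, SYNONYM_ROLE)
        else:
            self._add_role(subject, PREFERRED)

    def roles(self, label: str) -> set[str]:
        return self.nodes.get(label, set())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntegratedGraph):
            return NotImplemented
        return (
            self.problem_domain == other.problem_domain
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


def build_graph(
    sets: list[TerminologySet], domain: ProblemDomain | str
) -> IntegratedGraph:
    """Build the integrated graph for one problem domain.

    One edge per distinct (subject, object) pair per relation; a relation
    asserted by several terminology sets keeps one edge with the union of
    their IDs as provenance. Records belonging to the other domain are
    skipped (counted in a log line, not an error). Input sets are not
    mutated, and the result does not depend on their order.
    """
    domain = ProblemDomain(domain)
    graph = IntegratedGraph(problem_domain=domain)
    skipped = 0
    for ts in sets:
        for rec in ts.records:
            if rec.problem_domain != domain:
                skipped += 1
                continue
            tid = rec.terminology_id
            graph.add_edge(SUBCLASS, rec.preferred_label, rec.category_label, tid)
            for syn in rec.synonym_labels:
                graph.add_edge(SYNONYM, rec.preferred_label, syn, tid)
            for ncit in rec.cdrh_ncit_labels:
                graph.add_edge(CORRESPONDENCE, rec.preferred_label, ncit, tid)
            if rec.definition_text:
                graph.add_edge(DEFINITION, rec.preferred_label, rec.definition_text, tid)
    if skipped:
        logger.info("build_graph(%s): skipped %d records from the other domain",
                    domain.value, skipped)
    return graph


def merge_graphs(a: IntegratedGraph, b: IntegratedGraph) -> IntegratedGraph:
    """Union two graphs of the same domain (provenance sets are unioned)."""
    if a.problem_domain != b.problem_domain:
        raise ValueError("cannot merge graphs of different problem domains")
    out = IntegratedGraph(problem_domain=a.problem_domain)
    for g in (a, b):
        for pred, pairs in g.edges.items():
            for (subj, obj), prov in pairs.items():
                for tid in prov:
                    out.add_edge(pred, subj, obj, tid)
        for label, roles in g.nodes.items():
            for role in roles:
                out._add_role(label, role)
    return out


@dataclass(frozen=True)
class TermCounts:
    """Distinct-label tallies per role.

    ``combined`` counts distinct labels having the category or preferred
    role; synonym-only labels are excluded from it (they are alternative
    notations, not hierarchy members).
    """

    category: int
    preferred: int
    synonym: int
    combined: int


def count_terms(graph: IntegratedGraph) -> TermCounts:
    """Count distinct labels per role and combined (category ∪ preferred)."""
    cat = sum(1 for roles in graph.nodes.values() if CATEGORY in roles)
    pref = sum(1 for roles in graph.nodes.values() if PREFERRED in roles)
    syn = sum(1 for roles in graph.nodes.values() if SYNONYM_ROLE in roles)
    combined = sum(
        1 for roles in graph.nodes.values() if roles & {CATEGORY, PREFERRED}
    )
    return TermCounts(category=cat, preferred=pref, synonym=syn, combined=combined)


def count_relations(
    graph: IntegratedGraph, predicate: str, *, pre_dedup: bool = False
) -> int:
    """Count edges of one predicate.

    Default: distinct (subject, object) pairs after integration. With
    ``pre_dedup=True``: the sum of provenance multiplicities, i.e. the
    total number of assertions across all terminology sets before
    duplicates were merged.
    """
    if predicate not in PREDICATES:
        raise ValueError(f"unknown predicate: {predicate!r}")
    pairs = graph.edges[predicate]
    if pre_dedup:
        return sum(len(prov) for prov in pairs.values())
    return len(pairs)


def per_terminology_term_counts(graph: IntegratedGraph) -> dict[str, TermCounts]:
    """Reconstruct per-terminology role tallies from edge provenance.

    Summing the combined counts over terminology IDs gives the
    pre-integration term total (each set counted independently), the
    baseline against which integration's duplicate removal is measured.
    """
    cats: dict[str, set[str]] = {}
    prefs: dict[str, set[str]] = {}
    syns: dict[str, set[str]] = {}
    for (child, parent), prov in graph.edges[SUBCLASS].items():
        for tid in prov:
            prefs.setdefault(tid, set()).add(child)
            cats.setdefault(tid, set()).add(parent)
    for (subj, obj), prov in graph.edges[SYNONYM].items():
        for tid in prov:
            prefs.setdefault(tid, set()).add(subj)
            syns.setdefault(tid, set()).add(obj)
    for pred in (CORRESPONDENCE, DEFINITION):
        for (subj, _obj), prov in graph.edges[pred].items():
            for tid in prov:
                prefs.setdefault(tid, set()).add(subj)
    out: dict[str, TermCounts] = {}
    for tid in sorted(set(cats) | set(prefs) | set(syns)):
        c = cats.get(tid, set())
        p = prefs.get(tid, set())
        s = syns.get(tid, set())
        out[tid] = TermCounts(
            category=len(c), preferred=len(p), synonym=len(s), combined=len(c | p)
        )
    return out
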