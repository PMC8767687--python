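"""Independent brute-force oracles for the audit checks.

Deliberately naive: every oracle enumerates raw edge combinations directly,
without using node-role bookkeeping, finding sorting helpers, or networkx —
so agreement with the library is a two-route check, not a tautology.
"""

from __future__ import annotations

from termaudit.graph import (
    CORRESPONDENCE,
    DEFINITION,
    SUBCLASS,
    SYNONYM,
    IntegratedGraph,
)


def oracle_dual_role(graph: IntegratedGraph):
    sub = list(graph.edges[SUBCLASS].keys())
    patterns = set()
    terms = set()
    for (child1, parent1) in sub:
        # child1's parent edge makes child1 a preferred term
        for (child2, parent2) in sub:
            if parent2 == child1:  # child1 is also a category term
                patterns.add((parent1, child1, child2))
                terms.add(child1)
    return sorted(patterns), terms


def _is_preferred(graph: IntegratedGraph, label: str) -> bool:
    for pred in (SUBCLASS, SYNONYM, CORRESPONDENCE, DEFINITION):
        for (subj, _obj) in graph.edges[pred]:
            if subj == label:
                return True
    return False


def oracle_swap(graph: IntegratedGraph):
    syn = list(graph.edges[SYNONYM].keys())
    patterns = set()
    terms = set()
    for (p, x) in syn:
        if not _is_preferred(graph, x):
            continue
        terms.add(x)
        own = [s for (subj, s) in syn if subj == x]
        if own:
            for s in own:
                patterns.add((p, x, s))
        else:
            patterns.add((p, x, None))
    return sorted(patterns, key=lambda t: tuple("" if v is None else v for v in t)), terms


def _oracle_multiplicity(pairs):
    by_subject: dict[str, set[str]] = {}
    for (subj, obj) in pairs:
        by_subject.setdefault(subj, set()).add(obj)
    flagged = {
        subj: tuple(sorted(objs)) for subj, objs in by_subject.items() if len(objs) >= 2
    }
    max_mult = max((len(v) for v in flagged.values()), default=None)
    return sorted(flagged.items()), max_mult


def oracle_multi_parent(graph: IntegratedGraph):
    return _oracle_multiplicity(graph.edges[SUBCLASS].keys())


def oracle_multi_definition(graph: IntegratedGraph):
    return _oracle_multiplicity(graph.edges[DEFINITION].keys())


def oracle_multi_mapping(graph: IntegratedGraph):
    return _oracle_multiplicity(graph.edges[CORRESPONDENCE].keys())


def _hierarchy_labels(graph: IntegratedGraph) -> set[str]:
    labels = set()
    for (child, parent) in graph.edges[SUBCLASS]:
        labels.add(child)
        labels.add(parent)
    for pred in (SYNONYM, CORRESPONDENCE, DEFINITION):
        for (subj, _obj) in graph.edges[pred]:
            labels.add(subj)
    return labels


def oracle_cross_domain(device: IntegratedGraph, patient: IntegratedGraph):
    return sorted(_hierarchy_labels(device) & _hierarchy_labels(patient))


def oracle_cycles(graph: IntegratedGraph):
    """All elementary cycles by exhaustive DFS, canonical smallest-start rotation."""
    succ: dict[str, set[str]] = {}
    for (child, parent) in graph.edges[SUBCLASS]:
        succ.setdefault(child, set()).add(parent)
    nodes = sorted(set(succ) | {p for ps in succ.values() for p in ps})
    cycles = set()

    def dfs(start: str, node: str, path: list[str]):
        for nxt in sorted(succ.get(node, ())):
            if nxt == start:
                cycles.add(tuple(path))
            elif nxt > start and nxt not in path:
                dfs(start, nxt, path + [nxt])

    for start in nodes:
        dfs(start, start, [start])
    return sorted(cycles, key=lambda c: (len(c), c))
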