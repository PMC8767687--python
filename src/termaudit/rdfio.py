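"""RDF serialization of integrated graphs (Turtle / N-Triples).

The export exists for interoperability: the .ttl/.nt files load into any
SPARQL engine or ontology editor, so the audit queries can be reproduced
externally. Because integration merges terms by notation, a term's IRI is
a pure function of its normalized label: the percent-encoded label under a
per-domain namespace. Hierarchy edges use the standard ``rdfs:subClassOf``;
synonym and CDRH-NCIt correspondence edges use project predicates;
definitions attach as literals via ``rdfs:isDefinedBy``. Edge provenance
(which terminology sets assert a relation) is carried through standard RDF
reification with deterministic skolem statement IRIs, so an exported graph
re-imports with provenance intact.
"""

from __future__ import annotations

import hashlib
from urllib.parse import quote, unquote

from rdflib import Graph as RDFGraph
from rdflib import Literal, Namespace, RDF, RDFS, URIRef

from .graph import (
    CORRESPONDENCE,
    DEFINITION,
    SUBCLASS,
    SYNONYM,
    IntegratedGraph,
)
from .records import ProblemDomain

BASE = "https://w3id.org/termaudit/"
TA = Namespace(BASE + "schema#")

_PREDICATE_IRI = {
    SUBCLASS: RDFS.subClassOf,
    SYNONYM: TA.hasSynonym,
    CORRESPONDENCE: TA.correspondenceOf,
    DEFINITION: RDFS.isDefinedBy,
}
_IRI_PREDICATE = {v: k for k, v in _PREDICATE_IRI.items()}

#: predicates whose object is a term node rather than a literal
_NODE_OBJECT = {SUBCLASS, SYNONYM}

_FORMATS = {"turtle": "turtle", "ntriples": "nt11"}


def term_iri(domain: ProblemDomain, label: str) -> URIRef:
    """Mint the IRI for a term label: percent-encoded under the domain path."""
    return URIRef(f"{BASE}{domain.value}/{quote(label, safe='')}")


def _statement_iri(s: URIRef, p: URIRef, o) -> URIRef:
    digest = hashlib.sha1(
        f"{s.n3()} {p.n3()} {o.n3()}".encode("utf-8")
    ).hexdigest()
    return URIRef(f"{BASE}statement/{digest}")


def to_rdflib(graph: IntegratedGraph) -> RDFGraph:
    """Convert an IntegratedGraph to an rdflib Graph (with provenance)."""
    rg = RDFGraph()
    rg.bind("ta", TA)
    rg.bind("rdfs", RDFS)
    domain = graph.problem_domain
    triples = []
    labels: set[str] = set()
    for pred, pairs in graph.edges.items():
        p = _PREDICATE_IRI[pred]
        for (subj, obj), prov in pairs.items():
            s = term_iri(domain, subj)
            labels.add(subj)
            if pred in _NODE_OBJECT:
                o = term_iri(domain, obj)
                labels.add(obj)
            else:
                o = Literal(obj)
            triples.append((s, p, o))
            stmt = _statement_iri(s, p, o)
            triples.append((stmt, RDF.type, RDF.Statement))
            triples.append((stmt, RDF.subject, s))
            triples.append((stmt, RDF.predicate, p))
            triples.append((stmt, RDF.object, o))
            for tid in prov:
                triples.append((stmt, TA.sourceTerminology, Literal(tid)))
    for label in labels:
        triples.append((term_iri(domain, label), RDFS.label, Literal(label)))
    # insertion in sorted order keeps rdflib's serializers deterministic
    for t in sorted(triples, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
        rg.add(t)
    return rg


def export_rdf(graph: IntegratedGraph, format: str = "turtle") -> str:
    """Serialize a graph to Turtle or N-Triples text.

    Statement ordering is deterministic (sorted by subject, predicate,
    object): exporting the same graph twice yields byte-identical text.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose turtle or ntriples")
    rg = to_rdflib(graph)
    text = rg.serialize(format=_FORMATS[format])
    if format == "ntriples":
        lines = sorted(line for line in text.splitlines() if line.strip())
        text = "\n".join(lines) + "\n"
    return text


def _domain_and_label(iri: URIRef) -> tuple[ProblemDomain, str]:
    rest = str(iri)[len(BASE):]
    domain_part, _, encoded = rest.partition("/")
    return ProblemDomain(domain_part), unquote(encoded)


def import_rdf(serialized: str, format: str = "turtle") -> IntegratedGraph:
    """Parse Turtle/N-Triples produced by export_rdf back into a graph.

    Inverse of export_rdf: ``import_rdf(export_rdf(g, f), f) == g``.
    Raises ValueError on malformed syntax (rdflib reports the line) or on
    text that mixes problem domains.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose turtle or ntriples")
    rg = RDFGraph()
    rg.parse(data=serialized, format=_FORMATS[format])

    # provenance: statement IRI -> set of terminology ids
    prov_of: dict[URIRef, set[str]] = {}
    stmt_spo: dict[URIRef, tuple] = {}
    for stmt in rg.subjects(RDF.type, RDF.Statement):
        s = rg.value(stmt, RDF.subject)
        p = rg.value(stmt, RDF.predicate)
        o = rg.value(stmt, RDF.object)
        stmt_spo[stmt] = (s, p, o)
        prov_of[stmt] = {str(t) for t in rg.objects(stmt, TA.sourceTerminology)}

    domains: set[ProblemDomain] = set()
    edges: list[tuple[str, str, str, set[str]]] = []
    for stmt, (s, p, o) in stmt_spo.items():
        if p not in _IRI_PREDICATE:
            continue
        pred = _IRI_PREDICATE[p]
        dom, subj = _domain_and_label(s)
        domains.add(dom)
        if pred in _NODE_OBJECT:
            odom, obj = _domain_and_label(o)
            domains.add(odom)
        else:
            obj = str(o)
        edges.append((pred, subj, obj, prov_of[stmt]))

    if len(domains) > 1:
        raise ValueError(f"serialized graph mixes problem domains: {sorted(d.value for d in domains)}")
    domain = next(iter(domains)) if domains else ProblemDomain.DEVICE

    graph = IntegratedGraph(problem_domain=domain)
    for pred, subj, obj, prov in edges:
        for tid in sorted(prov):
            graph.add_edge(pred, subj, obj, tid)
    return graph
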