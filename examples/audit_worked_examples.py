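"""Audit the transcribed worked-example tables and print the headline numbers.

The fixtures encode the published example rows: a polyhierarchy table, a
multi-definition table, a multi-mapping table and the labels shared between
the device-problem and patient-problem vocabularies.
"""

from termaudit import (
    ProblemDomain,
    build_graph,
    check_cross_domain,
    check_multi_definition,
    check_multi_mapping,
    check_multi_parent,
    table_fixtures,
)

tables = table_fixtures()

r3 = check_multi_parent(build_graph(tables["table4"], ProblemDomain.DEVICE))
print(f"max category parents of one preferred term: {r3.max_multiplicity}")
worst = max(r3.findings, key=lambda f: len(f.pattern[1]))
print(f"  worst offender: {worst.pattern[0]} under {len(worst.pattern[1])} categories")

r4 = check_multi_definition(build_graph(tables["table5"], ProblemDomain.PATIENT))
by_label = {f.pattern[0]: f.pattern[1] for f in r4.findings}
print(f"distinct definitions of 感染: {len(by_label['感染'])}")
print("  (two of them differ only by a trailing 。 — exact-string distinctness)")

r5 = check_multi_mapping(build_graph(tables["table6"], ProblemDomain.PATIENT))
by_label = {f.pattern[0]: f.pattern[1] for f in r5.findings}
print(f"distinct CDRH-NCIt mappings of 穿孔: {len(by_label['穿孔'])}")

r6 = check_cross_domain(
    build_graph(tables["table7"], ProblemDomain.DEVICE),
    build_graph(tables["table7"], ProblemDomain.PATIENT),
)
terms = sorted(t for f in r6.findings for t in f.involved_terms)
print(f"labels used as hierarchy terms in BOTH domains: {len(terms)}")
print("  " + ", ".join(terms))
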