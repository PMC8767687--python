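"""Aggregate graph statistics and check results into an audit report.

The report mirrors what a terminology maintainer needs to act: how much
the notation-based integration deduplicated (term and relation tallies
before/after, reduction percentage), and per check the pattern count, the
unique flagged-term count, that count as a percentage of the integrated
vocabulary, the largest multiplicity observed, and the top offenders.

Percentage denominators: per-check percentages divide the unique flagged
term count by the post-integration combined term count (distinct category ∪
preferred labels) of the same domain. This denominator is stated in the
report itself.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

from .checks import (
    CROSS_DOMAIN,
    CYCLE,
    DUAL_ROLE,
    MULTI_DEFINITION,
    MULTI_MAPPING,
    MULTI_PARENT,
    SWAP,
    CheckResult,
)
from .graph import (
    PREDICATES,
    IntegratedGraph,
    count_relations,
    count_terms,
    per_terminology_term_counts,
)

SCHEMA_VERSION = "1.0"

_CHECK_NAMES = {
    DUAL_ROLE: "dual_role",
    SWAP: "preferred_synonym_swap",
    MULTI_PARENT: "multi_parent",
    MULTI_DEFINITION: "multi_definition",
    MULTI_MAPPING: "multi_mapping",
}


@dataclass
class AuditReport:
    """Schema-stable audit summary; ``data`` serializes as-is to JSON."""

    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.data, ensure_ascii=False, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AuditReport":
        return cls(data=json.loads(text))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AuditReport):
            return NotImplemented
        return self.data == other.data


def _round(x: float) -> float:
    return round(x, 2)


def _domain_summary(graph: IntegratedGraph) -> dict:
    post = count_terms(graph)
    per_tid = per_terminology_term_counts(graph)
    pre_cat = sum(tc.category for tc in per_tid.values())
    pre_pref = sum(tc.preferred for tc in per_tid.values())
    pre_combined = sum(tc.combined for tc in per_tid.values())
    degenerate = pre_combined == 0
    reduction = 0.0 if degenerate else _round(100.0 * (1 - post.combined / pre_combined))
    relations = {
        pred: {
            "pre": count_relations(graph, pred, pre_dedup=True),
            "post": count_relations(graph, pred),
        }
        for pred in PREDICATES
    }
    return {
        "terms": {
            "pre": {
                "category": pre_cat,
                "preferred": pre_pref,
                "combined": pre_combined,
            },
            "post": {
                "category": post.category,
                "preferred": post.preferred,
                "synonym": post.synonym,
                "combined": post.combined,
            },
            "reduction_percent": reduction,
        },
        "relations": relations,
        "degenerate_input": degenerate,
        "n_terminologies": len(per_tid),
    }


def _top_listing(result: CheckResult, k: int) -> list[dict]:
    # multiplicity = size of the sorted object tuple in the pattern
    items = [
        {"label": f.pattern[0], "multiplicity": len(f.pattern[1])}
        for f in result.findings
        if len(f.pattern) == 2 and isinstance(f.pattern[1], tuple)
    ]
    items.sort(key=lambda d: (-d["multiplicity"], d["label"]))
    return items[:k]


def _check_summary(result: CheckResult, combined_terms: int, top_k: int) -> dict:
    pct = 0.0
    if combined_terms > 0:
        pct = _round(100.0 * result.unique_term_count / combined_terms)
    out = {
        "pattern_count": result.pattern_count,
        "unique_term_count": result.unique_term_count,
        "percent_of_combined_terms": pct,
    }
    if result.alt_unique_term_count is not None:
        out["unique_term_count_with_partners"] = result.alt_unique_term_count
    if result.max_multiplicity is not None:
        out["max_multiplicity"] = result.max_multiplicity
    top = _top_listing(result, top_k)
    if top:
        out["top_terms"] = top
    return out


def summarize(
    device_graph: IntegratedGraph,
    patient_graph: IntegratedGraph,
    check_results: dict,
    *,
    top_k: int = 5,
) -> AuditReport:
    """Build the AuditReport from the two graphs and run_all_checks output.

    Deterministic and pure: the same inputs give a byte-identical JSON
    report. Listings are sorted by multiplicity descending then label, so
    the "largest number" offender per check is always first.
    """
    graphs = {"device": device_graph, "patient": patient_graph}
    domains = {name: _domain_summary(g) for name, g in graphs.items()}
    checks: dict = {}
    for cid, name in _CHECK_NAMES.items():
        checks[name] = {}
        for dom in ("device", "patient"):
            combined = domains[dom]["terms"]["post"]["combined"]
            checks[name][dom] = _check_summary(check_results[cid][dom], combined, top_k)
    cross: CheckResult = check_results[CROSS_DOMAIN]
    cycles = {
        dom: [list(f.pattern) for f in check_results[CYCLE][dom].findings]
        for dom in ("device", "patient")
    }
    data = {
        "schema_version": SCHEMA_VERSION,
        "percent_denominator": "post-integration combined (category ∪ preferred) term count per domain",
        "domains": domains,
        "checks": checks,
        "cross_domain": {
            "term_count": cross.unique_term_count,
            "terms": sorted(t for f in cross.findings for t in f.involved_terms),
        },
        "cycles": cycles,
    }
    return AuditReport(data=data)


def _markdown_table(headers: list[str], rows: list[list]) -> str:
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def render_markdown(report: AuditReport) -> str:
    d = report.data
    parts = ["# Terminology audit report", ""]
    parts.append("## Integration summary")
    rows = []
    for dom, s in d["domains"].items():
        t = s["terms"]
        rows.append(
            [dom, t["pre"]["combined"], t["post"]["combined"], t["reduction_percent"]]
        )
    parts.append(_markdown_table(["domain", "terms pre", "terms post", "reduction %"], rows))
    parts.append("")
    parts.append("## Relations (pre → post integration)")
    rows = []
    for dom, s in d["domains"].items():
        for pred, c in s["relations"].items():
            rows.append([dom, pred, c["pre"], c["post"]])
    parts.append(_markdown_table(["domain", "relation", "pre", "post"], rows))
    parts.append("")
    parts.append("## Checks")
    parts.append(f"Percentages use: {d['percent_denominator']}.")
    rows = []
    for name, per_dom in d["checks"].items():
        for dom, s in per_dom.items():
            rows.append(
                [
                    name,
                    dom,
                    s["pattern_count"],
                    s["unique_term_count"],
                    s["percent_of_combined_terms"],
                    s.get("max_multiplicity", ""),
                ]
            )
    parts.append(
        _markdown_table(
            ["check", "domain", "patterns", "unique terms", "% of terms", "max multiplicity"],
            rows,
        )
    )
    parts.append("")
    parts.append("## Cross-domain terms")
    parts.append(
        ", ".join(d["cross_domain"]["terms"]) if d["cross_domain"]["terms"] else "(none)"
    )
    parts.append("")
    parts.append("## Hierarchy cycles")
    for dom in ("device", "patient"):
        cycles = d["cycles"][dom]
        parts.append(f"- {dom}: " + ("; ".join(" → ".join(c) for c in cycles) or "(none)"))
    parts.append("")
    return "\n".join(parts)


def _csv_sections(report: AuditReport) -> dict[str, str]:
    d = report.data
    sections: dict[str, str] = {}

    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["domain", "terms_pre", "terms_post", "reduction_percent"])
    for dom, s in d["domains"].items():
        t = s["terms"]
        w.writerow([dom, t["pre"]["combined"], t["post"]["combined"], t["reduction_percent"]])
    sections["integration"] = buf.getvalue()

    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["domain", "relation", "pre", "post"])
    for dom, s in d["domains"].items():
        for pred, c in s["relations"].items():
            w.writerow([dom, pred, c["pre"], c["post"]])
    sections["relations"] = buf.getvalue()

    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(
        ["check", "domain", "pattern_count", "unique_term_count",
         "percent_of_combined_terms", "max_multiplicity"]
    )
    for name, per_dom in d["checks"].items():
        for dom, s in per_dom.items():
            w.writerow(
                [name, dom, s["pattern_count"], s["unique_term_count"],
                 s["percent_of_combined_terms"], s.get("max_multiplicity", "")]
            )
    sections["checks"] = buf.getvalue()

    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["term"])
    for t in d["cross_domain"]["terms"]:
        w.writerow([t])
    sections["cross_domain"] = buf.getvalue()

    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["domain", "cycle"])
    for dom in ("device", "patient"):
        for c in d["cycles"][dom]:
            w.writerow([dom, " → ".join(c)])
    sections["cycles"] = buf.getvalue()
    return sections


def write_report(
    report: AuditReport,
    path: str | Path,
    format: str = "json",
    *,
    bom: bool = False,
) -> list[Path]:
    """Write the report; returns the paths written.

    ``json``/``markdown`` write one file at ``path``. ``csv`` treats
    ``path`` as a directory and writes one file per section. ``bom``
    prepends a UTF-8 BOM to CSVs for spreadsheet compatibility with
    Japanese text.
    """
    path = Path(path)
    if format == "json":
        path.write_text(report.to_json() + "\n", encoding="utf-8")
        return [path]
    if format == "markdown":
        path.write_text(render_markdown(report), encoding="utf-8")
        return [path]
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        encoding = "utf-8-sig" if bom else "utf-8"
        written = []
        for name, text in _csv_sections(report).items():
            target = path / f"{name}.csv"
            target.write_text(text, encoding=encoding)
            written.append(target)
        return written
    raise ValueError(f"unknown report format: {format!r}")
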