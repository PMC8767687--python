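"""Record-level validation: collects issues, never raises."""

from __future__ import annotations

from dataclasses import dataclass

from .records import TerminologySet


@dataclass(frozen=True)
class ValidationIssue:
    """One machine-readable validation finding.

    ``severity`` is "warn" or "error"; ``code`` identifies the rule
    (duplicate-row, self-synonym, duplicate-synonym, blank-definition);
    ``terminology_id`` and ``labels`` locate the offending record.
    """

    code: str
    severity: str
    terminology_id: str
    labels: tuple[str, ...]
    message: str


def validate_records(sets: list[TerminologySet]) -> list[ValidationIssue]:
    """Check TerminologySets against the layout's record invariants.

    Reported issues:
      - duplicate-row (warn): two identical records in one set
      - self-synonym (error): a record lists its preferred term among its
        own synonyms
      - duplicate-synonym (warn): repeated synonym within one record
      - blank-definition (warn): record without a definition

    Pure collector: never mutates input, never raises.
    """
    issues: list[ValidationIssue] = []
    for ts in sets:
        seen_rows: set[tuple] = set()
        for rec in ts.records:
            key = (
                rec.problem_domain,
                rec.category_label,
                rec.preferred_label,
                tuple(rec.synonym_labels),
                rec.definition_text,
                tuple(rec.cdrh_ncit_labels),
            )
            if key in seen_rows:
                issues.append(
                    ValidationIssue(
                        code="duplicate-row",
                        severity="warn",
                        terminology_id=ts.terminology_id,
                        labels=(rec.category_label, rec.preferred_label),
                        message="identical record appears more than once",
                    )
                )
            else:
                seen_rows.add(key)
            if rec.preferred_label in rec.synonym_labels:
                issues.append(
                    ValidationIssue(
                        code="self-synonym",
                        severity="error",
                        terminology_id=ts.terminology_id,
                        labels=(rec.preferred_label,),
                        message="preferred term listed among its own synonyms",
                    )
                )
            if len(set(rec.synonym_labels)) != len(rec.synonym_labels):
                issues.append(
                    ValidationIssue(
                        code="duplicate-synonym",
                        severity="warn",
                        terminology_id=ts.terminology_id,
                        labels=(rec.preferred_label,),
                        message="synonym list contains duplicates",
                    )
                )
            if not rec.definition_text:
                issues.append(
                    ValidationIssue(
                        code="blank-definition",
                        severity="warn",
                        terminology_id=ts.terminology_id,
                        labels=(rec.preferred_label,),
                        message="record has no definition",
                    )
                )
    return issues
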