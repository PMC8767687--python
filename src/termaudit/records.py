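"""Core record types and label normalization.

A terminology set is a two-level controlled vocabulary: upper-level
*category terms* group lower-level *preferred terms*; each preferred term
may carry synonyms, a free-text definition, and mappings to the CDRH-NCIt
terminology. Integration across many independently authored sets merges
terms purely by notation, so notation must first be made canonical.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from enum import Enum


class ProblemDomain(str, Enum):
    """The two sections every terminology set carries."""

    DEVICE = "device"
    PATIENT = "patient"


#: accepted spellings for the problem-domain column, lower-cased
_DOMAIN_ALIASES = {
    "device": ProblemDomain.DEVICE,
    "medical device problem": ProblemDomain.DEVICE,
    "medical device problems": ProblemDomain.DEVICE,
    "医療機器不具合": ProblemDomain.DEVICE,
    "不具合": ProblemDomain.DEVICE,
    "patient": ProblemDomain.PATIENT,
    "patient problem": ProblemDomain.PATIENT,
    "patient problems": ProblemDomain.PATIENT,
    "健康被害": ProblemDomain.PATIENT,
}


def parse_domain(value: str) -> ProblemDomain:
    """Map a problem-domain cell value to the enum.

    Raises ValueError for unrecognized values.
    """
    key = value.strip().lower()
    try:
        return _DOMAIN_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized problem-domain value: {value!r}") from None


class EmptyLabelError(ValueError):
    """A label is empty after normalization."""


def normalize_label(
    raw: str,
    *,
    width_fold: bool = False,
    case_fold: bool = False,
) -> str:
    """Canonicalize a term label for notation-based merging.

    Applies Unicode canonical composition (NFC) and strips leading/trailing
    whitespace, including the ideographic space U+3000. Internal characters,
    width, case and punctuation are preserved by default: two labels merge
    only when they are the same string after this minimal canonicalization.
    Optional ``width_fold`` (NFKC) and ``case_fold`` flags exist for
    terminologies that mix full/half-width or Latin case, but both default
    off because distinctness of near-identical strings (e.g. definitions
    differing only in a trailing "。") is itself a signal the audit reports.

    Idempotent: ``normalize_label(normalize_label(x)) == normalize_label(x)``.

    Raises EmptyLabelError if the result is empty.
    """
    form = "NFKC" if width_fold else "NFC"
    label = unicodedata.normalize(form, raw).strip()
    if case_fold:
        label = label.casefold()
    if not label:
        raise EmptyLabelError(f"label is empty after normalization: {raw!r}")
    return label


def normalize_text(raw: str) -> str:
    """Normalize free text (definitions): NFC + trim only.

    Unlike labels, an empty result is allowed (a record may lack a
    definition) and punctuation is always significant.
    """
    return unicodedata.normalize("NFC", raw).strip()


@dataclass
class TermRecord:
    """One row of a terminology table.

    Valid records satisfy: non-empty ``terminology_id``, ``category_label``
    and ``preferred_label``; ``synonym_labels`` free of duplicates and of
    the preferred label itself. Violations are reported by
    :func:`termaudit.validate.validate_records` rather than rejected here,
    because detecting them in published data is part of the audit.
    """

    terminology_id: str
    problem_domain: ProblemDomain
    category_label: str
    preferred_label: str
    synonym_labels: list[str] = field(default_factory=list)
    definition_text: str = ""
    cdrh_ncit_labels: list[str] = field(default_factory=list)


@dataclass
class TerminologySet:
    """One per-device-group terminology: an ID, a group name, its records.

    A set normally covers both problem domains (each published terminology
    has a medical-device-problem and a patient-problem section).
    """

    terminology_id: str
    device_group_name: str = ""
    records: list[TermRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.terminology_id != self.terminology_id:
                raise ValueError(
                    f"record terminology_id {rec.terminology_id!r} does not "
                    f"match set {self.terminology_id!r}"
                )
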