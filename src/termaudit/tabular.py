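"""Reading and writing terminology tables (CSV/TSV).

The published layout is seven columns per row: terminology ID, problem
domain, category term, preferred term, synonyms, definition, CDRH-NCIt
term(s). Synonym and CDRH-NCIt cells hold comma-separated lists in which
items containing the delimiter are double-quoted (so
``"Vessels, perforation of", perforation`` is two items, not three).
Header names are matched through a configurable mapping so Japanese and
English headers both work.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .records import (
    EmptyLabelError,
    TermRecord,
    TerminologySet,
    normalize_label,
    normalize_text,
    parse_domain,
)

#: canonical field keys, in column order
FIELD_KEYS = (
    "terminology_id",
    "problem_domain",
    "category_label",
    "preferred_label",
    "synonym_labels",
    "definition_text",
    "cdrh_ncit_labels",
)

#: header spellings accepted out of the box (lower-cased)
DEFAULT_HEADER_ALIASES: dict[str, str] = {
    "terminology id": "terminology_id",
    "terminology_id": "terminology_id",
    "用語集id": "terminology_id",
    "problem domain": "problem_domain",
    "problem_domain": "problem_domain",
    "medical device problems/patient problems": "problem_domain",
    "医療機器不具合/健康被害": "problem_domain",
    "区分": "problem_domain",
    "category term": "category_label",
    "category terms": "category_label",
    "category_label": "category_label",
    "カテゴリー用語": "category_label",
    "preferred term": "preferred_label",
    "preferred terms": "preferred_label",
    "preferred_label": "preferred_label",
    "基本用語": "preferred_label",
    "synonym": "synonym_labels",
    "synonyms": "synonym_labels",
    "synonym_labels": "synonym_labels",
    "同義語": "synonym_labels",
    "definition": "definition_text",
    "definitions": "definition_text",
    "definition_text": "definition_text",
    "定義": "definition_text",
    "cdrh-ncit": "cdrh_ncit_labels",
    "cdrh_ncit": "cdrh_ncit_labels",
    "cdrh_ncit_labels": "cdrh_ncit_labels",
}


class SchemaError(ValueError):
    """A required column is missing from the header."""


class RowError(ValueError):
    """A row holds an unparseable or invalid value."""

    def __init__(self, message: str, row_number: int):
        super().__init__(f"row {row_number}: {message}")
        self.row_number = row_number


@dataclass
class TableDialect:
    """How a terminology table is laid out on disk.

    ``delimiter`` separates columns; ``list_delimiter`` separates items
    inside the synonym and CDRH-NCIt cells (double quotes protect items
    containing it). ``header_aliases`` extends the built-in header mapping.
    ``width_fold``/``case_fold`` forward to label normalization and both
    default off: notation equality is exact string equality after NFC + trim.
    """

    delimiter: str = ","
    list_delimiter: str = ","
    header_aliases: dict[str, str] = field(default_factory=dict)
    width_fold: bool = False
    case_fold: bool = False

    def resolve_header(self, name: str) -> str | None:
        key = name.strip().lower().lstrip("﻿")
        if key in self.header_aliases:
            return self.header_aliases[key]
        return DEFAULT_HEADER_ALIASES.get(key)

    def normalize(self, raw: str) -> str:
        return normalize_label(
            raw, width_fold=self.width_fold, case_fold=self.case_fold
        )


def load_dialect(path: str | Path) -> TableDialect:
    """Load a TableDialect from a YAML file.

    Recognized keys: delimiter, list_delimiter, header_aliases (mapping),
    width_fold, case_fold. Missing keys take the defaults.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"dialect file {path} must hold a mapping")
    known = {"delimiter", "list_delimiter", "header_aliases", "width_fold", "case_fold"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown dialect keys: {sorted(unknown)}")
    aliases = {
        str(k).strip().lower(): str(v)
        for k, v in (data.get("header_aliases") or {}).items()
    }
    return TableDialect(
        delimiter=data.get("delimiter", ","),
        list_delimiter=data.get("list_delimiter", ","),
        header_aliases=aliases,
        width_fold=bool(data.get("width_fold", False)),
        case_fold=bool(data.get("case_fold", False)),
    )


def split_cell(cell: str, delimiter: str = ",") -> list[str]:
    """Split an intra-cell list, honoring double-quoted items.

    ``'"Vessels, perforation of", cardiac perforation, perforation, injury'``
    yields four items. Empty items are dropped.
    """
    if not cell.strip():
        return []
    reader = csv.reader(
        io.StringIO(cell), delimiter=delimiter, quotechar='"', skipinitialspace=True
    )
    row = next(reader, [])
    return [item for item in (piece.strip() for piece in row) if item]


def join_cell(items: list[str], delimiter: str = ",") -> str:
    """Inverse of split_cell: quote items containing the delimiter or quotes."""
    out = []
    for item in items:
        if delimiter in item or '"' in item:
            out.append('"' + item.replace('"', '""') + '"')
        else:
            out.append(item)
    return (delimiter + " ").join(out)


def _dedup_keep_order(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def read_terminology_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[TerminologySet]:
    """Read a terminology table into one TerminologySet per terminology ID.

    Every label passes through normalization; synonym and CDRH-NCIt cells
    are split per the dialect's intra-cell delimiter; exact duplicate
    synonyms within a cell are collapsed. Rows repeating the same
    (category, preferred) pair to carry extra synonyms are accepted and
    left as separate records (the graph builder merges them).

    Raises SchemaError if a required column is missing, RowError for an
    unparseable domain or an empty category/preferred cell.
    """
    dialect = dialect or TableDialect()
    with open(path, encoding="utf-8-sig", newline="") as fh:
        return _read_rows(csv.reader(fh, delimiter=dialect.delimiter), dialect)


def read_terminology_text(
    text: str, dialect: TableDialect | None = None
) -> list[TerminologySet]:
    """Like read_terminology_table but from an in-memory string."""
    dialect = dialect or TableDialect()
    return _read_rows(csv.reader(io.StringIO(text), delimiter=dialect.delimiter), dialect)


def _read_rows(reader, dialect: TableDialect) -> list[TerminologySet]:
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("file is empty (no header row)") from None

    col_of: dict[str, int] = {}
    for idx, name in enumerate(header):
        key = dialect.resolve_header(name)
        if key is not None and key not in col_of:
            col_of[key] = idx
    missing = [k for k in FIELD_KEYS if k not in col_of]
    # definition and mapping columns are optional in degraded inputs
    required = [
        m for m in missing if m not in ("definition_text", "cdrh_ncit_labels")
    ]
    if required:
        raise SchemaError(f"missing required column(s): {', '.join(required)}")

    def cell(row: list[str], key: str) -> str:
        idx = col_of.get(key)
        if idx is None or idx >= len(row):
            return ""
        return row[idx]

    sets: dict[str, TerminologySet] = {}
    for row_number, row in enumerate(reader, start=2):
        if not any(c.strip() for c in row):
            continue
        tid = cell(row, "terminology_id").strip()
        if not tid:
            raise RowError("empty terminology ID", row_number)
        try:
            domain = parse_domain(cell(row, "problem_domain"))
        except ValueError as exc:
            raise RowError(str(exc), row_number) from None
        try:
            category = dialect.normalize(cell(row, "category_label"))
        except EmptyLabelError:
            raise RowError("empty category term", row_number) from None
        try:
            preferred = dialect.normalize(cell(row, "preferred_label"))
        except EmptyLabelError:
            raise RowError("empty preferred term", row_number) from None
        synonyms = _dedup_keep_order(
            [
                dialect.normalize(s)
                for s in split_cell(cell(row, "synonym_labels"), dialect.list_delimiter)
            ]
        )
        ncit = _dedup_keep_order(
            [
                normalize_text(s)
                for s in split_cell(cell(row, "cdrh_ncit_labels"), dialect.list_delimiter)
            ]
        )
        record = TermRecord(
            terminology_id=tid,
            problem_domain=domain,
            category_label=category,
            preferred_label=preferred,
            synonym_labels=synonyms,
            definition_text=normalize_text(cell(row, "definition_text")),
            cdrh_ncit_labels=ncit,
        )
        if tid not in sets:
            sets[tid] = TerminologySet(terminology_id=tid)
        sets[tid].records.append(record)
    return [sets[tid] for tid in sets]


def write_terminology_table(
    sets: list[TerminologySet],
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    bom: bool = False,
) -> None:
    """Write TerminologySets back to the tabular layout.

    Round-trip safe with read_terminology_table. ``bom`` prepends a UTF-8
    BOM for spreadsheet applications that need it for Japanese text.
    """
    dialect = dialect or TableDialect()
    encoding = "utf-8-sig" if bom else "utf-8"
    with open(path, "w", encoding=encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(FIELD_KEYS)
        for ts in sets:
            for rec in ts.records:
                writer.writerow(
                    [
                        rec.terminology_id,
                        rec.problem_domain.value,
                        rec.category_label,
                        rec.preferred_label,
                        join_cell(rec.synonym_labels, dialect.list_delimiter),
                        rec.definition_text,
                        join_cell(rec.cdrh_ncit_labels, dialect.list_delimiter),
                    ]
                )
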