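"""Table ingest: grouping, cell splitting, dialects, round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termaudit import (
    ProblemDomain,
    TableDialect,
    load_dialect,
    read_terminology_table,
    read_terminology_text,
    write_terminology_table,
)
from termaudit.records import TermRecord, TerminologySet
from termaudit.tabular import RowError, SchemaError, join_cell, split_cell

HEADER = (
    "terminology_id,problem_domain,category_label,preferred_label,"
    "synonym_labels,definition_text,cdrh_ncit_labels\n"
)


def test_groups_rows_by_terminology_id():
    text = HEADER + (
        "A01-1,device,故障,バッテリ不良,,,\n"
        "B02-1,patient,炎症,痛み,,,\n"
        "A01-1,device,故障,早期放電,,,\n"
    )
    sets = read_terminology_text(text)
    assert [s.terminology_id for s in sets] == ["A01-1", "B02-1"]
    assert len(sets[0].records) == 2


def test_quoted_intra_cell_items_stay_whole():
    text = HEADER + (
        'T6,patient,T6C-01,穿孔,,,'
        '"""Vessels, perforation of"", cardiac perforation, perforation, injury"\n'
    )
    [ts] = read_terminology_text(text)
    assert ts.records[0].cdrh_ncit_labels == [
        "Vessels, perforation of",
        "cardiac perforation",
        "perforation",
        "injury",
    ]


def test_header_only_file_gives_empty_list():
    assert read_terminology_text(HEADER) == []


def test_japanese_and_english_headers_accepted():
    text = (
        "用語集ID,医療機器不具合/健康被害,カテゴリー用語,基本用語,同義語,定義,CDRH-NCIt\n"
        "A01-1,医療機器不具合,故障,バッテリ不良,バッテリー不良,定義文。,NC battery\n"
    )
    [ts] = read_terminology_text(text)
    rec = ts.records[0]
    assert rec.problem_domain is ProblemDomain.DEVICE
    assert rec.synonym_labels == ["バッテリー不良"]
    assert rec.definition_text == "定義文。"


def test_labels_are_normalized_on_read():
    text = HEADER + "A,device, 故障　,　バッテリ不良 ,　はがれ ,,\n"
    [ts] = read_terminology_text(text)
    rec = ts.records[0]
    assert (rec.category_label, rec.preferred_label) == ("故障", "バッテリ不良")
    assert rec.synonym_labels == ["はがれ"]


def test_duplicate_synonyms_collapsed_on_read():
    text = HEADER + "A,device,故障,不良,\"はがれ, はがれ, 剥離\",,\n"
    [ts] = read_terminology_text(text)
    assert ts.records[0].synonym_labels == ["はがれ", "剥離"]


def test_missing_required_column_names_it():
    with pytest.raises(SchemaError, match="preferred_label"):
        read_terminology_text(
            "terminology_id,problem_domain,category_label\nA,device,x\n"
        )


def test_bad_domain_value_reports_row_number():
    text = HEADER + "A,device,故障,不良,,,\nA,machine,故障,不良,,,\n"
    with pytest.raises(RowError, match="row 3"):
        read_terminology_text(text)


def test_empty_preferred_cell_reports_row_number():
    text = HEADER + "A,device,故障, ,,,\n"
    with pytest.raises(RowError, match="row 2.*preferred"):
        read_terminology_text(text)


def test_tsv_and_semicolon_list_dialect():
    dialect = TableDialect(delimiter="\t", list_delimiter=";")
    text = HEADER.replace(",", "\t") + "A\tdevice\t故障\t不良\tはがれ; 剥離\t\t\n"
    [ts] = read_terminology_text(text, dialect)
    assert ts.records[0].synonym_labels == ["はがれ", "剥離"]


def test_load_dialect_yaml(tmp_path):
    path = tmp_path / "dialect.yaml"
    path.write_text(
        "delimiter: \"\\t\"\nlist_delimiter: \";\"\n"
        "header_aliases:\n  用語番号: terminology_id\nwidth_fold: true\n",
        encoding="utf-8",
    )
    d = load_dialect(path)
    assert d.delimiter == "\t" and d.list_delimiter == ";"
    assert d.resolve_header("用語番号") == "terminology_id"
    assert d.width_fold and not d.case_fold
    with pytest.raises(ValueError, match="unknown dialect"):
        path.write_text("delimeter: ','\n", encoding="utf-8")
        load_dialect(path)


def test_split_join_cell_inverse():
    items = ["Vessels, perforation of", "perforation", 'say "hi"']
    assert split_cell(join_cell(items)) == items


_label = st.text(
    alphabet=st.sampled_from("破損不良感染ABCxyz0"), min_size=1, max_size=6
)


@st.composite
def _sets_strategy(draw):
    n = draw(st.integers(1, 5))
    sets = {}
    for _ in range(n):
        tid = draw(st.sampled_from(["A01", "B02", "C03"]))
        pref = draw(_label)
        syns = draw(
            st.lists(_label.filter(lambda s: s != pref), max_size=3, unique=True)
        )
        rec = TermRecord(
            terminology_id=tid,
            problem_domain=draw(st.sampled_from(list(ProblemDomain))),
            category_label=draw(_label),
            preferred_label=pref,
            synonym_labels=syns,
            definition_text=draw(st.sampled_from(["", "定義。", "定義", "def, with comma"])),
            cdrh_ncit_labels=draw(st.lists(_label, max_size=2, unique=True)),
        )
        sets.setdefault(tid, TerminologySet(terminology_id=tid)).records.append(rec)
    return list(sets.values())


@given(_sets_strategy())
@settings(max_examples=50, derandomize=True)
def test_write_read_round_trip(tmp_path_factory, sets):
    path = tmp_path_factory.mktemp("rt") / "table.csv"
    write_terminology_table(sets, path)
    back = read_terminology_table(path)
    assert [s.records for s in back] == [s.records for s in sets]


def test_read_is_order_stable(tmp_path, tables):
    path = tmp_path / "t.csv"
    write_terminology_table(tables["table2"], path)
    assert read_terminology_table(path) == read_terminology_table(path)
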