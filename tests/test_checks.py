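"""Audit checks: worked examples, brute-force oracle equivalence, purity."""

import copy

import pytest
from conftest import make_record, make_set, random_graph
from oracles import (
    oracle_cross_domain,
    oracle_dual_role,
    oracle_multi_definition,
    oracle_multi_mapping,
    oracle_multi_parent,
    oracle_swap,
)

from termaudit import (
    ProblemDomain,
    build_graph,
    check_cross_domain,
    check_dual_role,
    check_multi_definition,
    check_multi_mapping,
    check_multi_parent,
    check_preferred_synonym_swap,
    findings_to_csv,
    findings_to_jsonl,
    run_all_checks,
)

DEV = ProblemDomain.DEVICE
PAT = ProblemDomain.PATIENT


# ---------------------------------------------------------------- check 1

def test_dual_role_on_battery_chain(tables):
    g = build_graph(tables["table2"], DEV)
    r = check_dual_role(g)
    assert ("故障", "バッテリ不良", "早期放電") in [f.pattern for f in r.findings]
    # ヒューズ切れ, アラーム異常, 不明, バッテリ不良, 誤穿刺
    assert r.unique_term_count == 5


def test_identical_label_sub_flag():
    g = build_graph([make_set("S1", [make_record(cat="誤穿刺", pref="誤穿刺")])], DEV)
    [f] = check_dual_role(g).findings
    assert f.pattern == ("誤穿刺", "誤穿刺", "誤穿刺")
    assert "identical-label" in f.flags


def test_plain_two_level_record_is_consistent():
    g = build_graph([make_set("S1", [make_record(cat="A", pref="B")])], DEV)
    assert check_dual_role(g).pattern_count == 0


def test_dual_role_patterns_are_context_cross_product():
    records = [
        make_record(tid="S1", cat="P1", pref="T"),
        make_record(tid="S1", cat="P2", pref="T"),
        make_record(tid="S1", cat="T", pref="C1"),
        make_record(tid="S1", cat="T", pref="C2"),
        make_record(tid="S1", cat="T", pref="C3"),
    ]
    r = check_dual_role(build_graph([make_set("S1", records)], DEV))
    assert r.pattern_count == 6 and r.unique_term_count == 1


# ---------------------------------------------------------------- check 2

def test_swap_detected_both_directions(tables):
    g = build_graph(tables["table3"], DEV)
    r = check_preferred_synonym_swap(g)
    patterns = [f.pattern for f in r.findings]
    assert ("剥離", "はがれ", "剥離") in patterns
    flagged = {t for f in r.findings for t in f.involved_terms}
    assert {"剥離", "はがれ"} <= flagged


def test_synonym_never_preferred_is_clean():
    g = build_graph([make_set("S1", [make_record(pref="A", syns=["B"])])], DEV)
    assert check_preferred_synonym_swap(g).pattern_count == 0


def test_swapped_term_without_own_synonyms_gets_open_pattern():
    records = [
        make_record(tid="S1", cat="C1", pref="P", syns=["X"]),
        make_record(tid="S1", cat="C2", pref="X"),
    ]
    r = check_preferred_synonym_swap(build_graph([make_set("S1", records)], DEV))
    assert [f.pattern for f in r.findings] == [("P", "X", None)]


# ------------------------------------------------------------- checks 3-5

def test_multi_parent_deformation_row(tables):
    r = check_multi_parent(build_graph(tables["table4"], DEV))
    assert r.max_multiplicity == 11
    by_label = {f.pattern[0]: f.pattern[1] for f in r.findings}
    assert len(by_label["変形"]) == 11
    assert by_label["アーチファクト"] == ("アーチファクト", "異常画像")  # self-parent counts


def test_single_parent_everywhere_is_clean():
    g = build_graph([make_set("S1", [make_record(cat="A", pref="B")])], DEV)
    assert check_multi_parent(g).pattern_count == 0


def test_multi_definition_counts_exact_strings(tables):
    r = check_multi_definition(build_graph(tables["table5"], PAT))
    by_label = {f.pattern[0]: f.pattern[1] for f in r.findings}
    # trailing 。 alone separates two of the eight
    assert len(by_label["感染"]) == 8 and r.max_multiplicity == 8


def test_fuse_blown_two_definitions(tables):
    r = check_multi_definition(build_graph(tables["table5"], DEV))
    by_label = {f.pattern[0]: f.pattern[1] for f in r.findings}
    assert len(by_label["ヒューズ切れ"]) == 2


def test_multi_mapping_default_case_sensitive(tables):
    g = build_graph(tables["table6"], DEV)
    r = check_multi_mapping(g)
    by_label = {f.pattern[0]: f.pattern[1] for f in r.findings}
    assert "Material deformation" in by_label["変形"]
    assert "material deformation" in by_label["変形"]
    folded = {f.pattern[0]: f.pattern[1] for f in
              check_multi_mapping(g, case_insensitive=True).findings}
    assert len(folded["変形"]) == len(by_label["変形"]) - 1


def test_perforation_has_four_targets(tables):
    r = check_multi_mapping(build_graph(tables["table6"], PAT))
    by_label = {f.pattern[0]: f.pattern[1] for f in r.findings}
    assert len(by_label["穿孔"]) == 4
    assert len(by_label["アレルギー反応"]) == 2


# ---------------------------------------------------------------- check 6

def test_cross_domain_flags_exactly_the_shared_hierarchy_terms(tables):
    dev = build_graph(tables["table7"], DEV)
    pat = build_graph(tables["table7"], PAT)
    r = check_cross_domain(dev, pat)
    flagged = {t for f in r.findings for t in f.involved_terms}
    assert len(flagged) == 8 and "損傷" in flagged
    assert "装置固有事象" not in flagged  # domain-unique distractor
    assert "共通別名" not in flagged  # synonym-only in both domains


def test_disjoint_vocabularies_are_clean():
    dev = build_graph([make_set("S1", [make_record(cat="A", pref="B")])], DEV)
    pat = build_graph(
        [make_set("S1", [make_record(domain=PAT, cat="C", pref="D")])], PAT
    )
    assert check_cross_domain(dev, pat).pattern_count == 0


# --------------------------------------------------- properties & oracles

@pytest.mark.parametrize("seed", range(20))
def test_checks_agree_with_brute_force_oracles(seed):
    g = random_graph(seed)
    r1 = check_dual_role(g)
    patterns, terms = oracle_dual_role(g)
    assert [f.pattern for f in r1.findings] == patterns
    assert r1.unique_term_count == len(terms)

    r2 = check_preferred_synonym_swap(g)
    patterns, terms = oracle_swap(g)
    none_last = lambda t: tuple("" if v is None else v for v in t)
    assert sorted((f.pattern for f in r2.findings), key=none_last) == patterns
    assert r2.unique_term_count == len(terms)

    for check, oracle in (
        (check_multi_parent, oracle_multi_parent),
        (check_multi_definition, oracle_multi_definition),
        (check_multi_mapping, oracle_multi_mapping),
    ):
        r = check(g)
        flagged, max_mult = oracle(g)
        assert [(f.pattern[0], f.pattern[1]) for f in r.findings] == flagged
        assert r.max_multiplicity == max_mult

    pat_g = random_graph(seed + 1000, domain=PAT)
    r6 = check_cross_domain(g, pat_g)
    assert sorted(t for f in r6.findings for t in f.involved_terms) == oracle_cross_domain(
        g, pat_g
    )


@pytest.mark.parametrize("seed", range(8))
def test_checks_are_pure_and_deterministic(seed):
    g = random_graph(seed)
    snapshot = copy.deepcopy(g)
    first = run_all_checks(g, random_graph(seed + 500, domain=PAT))
    second = run_all_checks(g, random_graph(seed + 500, domain=PAT))
    assert g == snapshot
    for cid in first:
        if isinstance(first[cid], dict):
            for dom in first[cid]:
                assert first[cid][dom].findings == second[cid][dom].findings
        else:
            assert first[cid].findings == second[cid].findings


@pytest.mark.parametrize("seed", range(10))
def test_unique_terms_never_exceed_patterns(seed):
    g = random_graph(seed)
    for r in (check_dual_role(g), check_preferred_synonym_swap(g)):
        if r.pattern_count > 0:
            assert r.unique_term_count <= r.pattern_count


def test_findings_provenance_names_disagreeing_sets():
    s1 = make_set("A01", [make_record(tid="A01", cat="故障", pref="バッテリ不良")])
    s2 = make_set("B02", [make_record(tid="B02", cat="バッテリ不良", pref="早期放電")])
    [f] = check_dual_role(build_graph([s1, s2], DEV)).findings
    assert f.provenance == frozenset({"A01", "B02"})


def test_findings_export_formats(tables):
    g = build_graph(tables["table4"], DEV)
    findings = check_multi_parent(g).findings
    csv_text = findings_to_csv(findings)
    assert csv_text.startswith("check_id,pattern")
    assert "変形" in csv_text
    jsonl = findings_to_jsonl(findings)
    assert jsonl.count("\n") == len(findings)
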