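"""Ready-made fixtures encoding the published worked examples.

These transcribe the example rows printed with the original terminology
audit (dual-role hierarchy triples, preferred/synonym swaps, polyhierarchy
rows, multi-definition and multi-mapping sets, and the eight labels shared
between the device-problem and patient-problem vocabularies), so the whole
pipeline can be exercised and its headline numbers reproduced without
downloading the full terminology release.

Scaffolding labels that the printed tables do not provide (every record
needs a category term, for instance) use clearly synthetic tokens such as
``T3C-01``.
"""

from __future__ import annotations

from .records import ProblemDomain, TermRecord, TerminologySet

DEV = ProblemDomain.DEVICE
PAT = ProblemDomain.PATIENT


def _sets(records: list[TermRecord]) -> list[TerminologySet]:
    by_tid: dict[str, TerminologySet] = {}
    for rec in records:
        if rec.terminology_id not in by_tid:
            by_tid[rec.terminology_id] = TerminologySet(
                terminology_id=rec.terminology_id
            )
        by_tid[rec.terminology_id].records.append(rec)
    return [by_tid[tid] for tid in sorted(by_tid)]


def _rec(tid, domain, cat, pref, syns=(), definition="", ncit=()):
    return TermRecord(
        terminology_id=tid,
        problem_domain=domain,
        category_label=cat,
        preferred_label=pref,
        synonym_labels=list(syns),
        definition_text=definition,
        cdrh_ncit_labels=list(ncit),
    )


# (category term, dual-role term, preferred term): one terminology places the
# middle label below the left one, another places the right label below it
_TABLE2_DEVICE = [
    ("電気的不良", "ヒューズ切れ", "ヒューズ溶断"),
    ("機器不良", "アラーム異常", "異常検知不可"),
    ("不明", "不明", "原因不明"),
    ("故障", "バッテリ不良", "早期放電"),
    ("動作不良", "バッテリ不良", "バッテリ駆動不良"),
    ("誤穿刺", "誤穿刺", "誤穿刺"),
]
_TABLE2_PATIENT = [
    ("アレルギー症状", "かゆみ", "そう痒感"),
    ("機能性障害", "呼吸不全", "動脈血酸素飽和度低下"),
    ("炎症", "痛み", "のどの痛み"),
    ("炎症症状", "皮膚炎", "痒み"),
    ("損傷", "外傷", "損傷"),
]

# (preferred term, swapped term, synonym): the middle label is a synonym in
# one terminology and a preferred term in another
_TABLE3_DEVICE = [
    ("剥離", "はがれ", "剥離"),
    ("変形", "へこみ", "陥没"),
    ("変形", "折れ", "折損"),
    ("変形", "曲がり", "湾曲"),
    ("誤作動", "誤動作", "意図しない動作"),
    ("挿入不能", "迷入", "網膜下迷入"),
]
_TABLE3_PATIENT = [
    ("意図しない組織損傷", "裂傷", "切り傷"),
    ("残留", "遺残", "異物残存"),
    ("感染症", "感染", "患者感染"),
    ("感染症", "感染", "合併症"),
]

# preferred term -> all category terms it appears under
_TABLE4_DEVICE = {
    "アーチファクト": ["アーチファクト", "異常画像"],
    "バッテリ不良": ["充電不良", "動作不良", "故障"],
    "劣化": ["経時変化", "故障", "破損", "不良"],
    "変形": [
        "故障", "破損", "成形不良", "変形不良", "コンタクトレンズ不良",
        "分注ノズル折損・変形", "機械的不良", "不良", "損傷",
        "意図しない効果", "品質不良",
    ],
}
_TABLE4_PATIENT = {
    "かぶれ": ["炎症症状", "炎症", "皮膚炎", "かぶれ"],
    "骨折": ["骨折", "外傷", "損傷", "組織損傷", "組織障害"],
    "神経障害": ["組織損傷", "機能性障害"],
    "失明": ["視機能障害", "視力障害", "失明"],
    "アレルギー反応": [
        "感染", "炎症", "ショック", "アレルギー症状", "眼疾患",
        "損傷", "アレルギー反応",
    ],
}

# preferred term -> all definition strings (trailing punctuation significant)
_TABLE5_DEVICE = {
    "アーチファクト": [
        "信号処理などで、観測や解析の段階で発生したデータのエラーや信号のゆがみが画像に混入すること。",
        "目的としない信号が表示されること",
    ],
    "ヒューズ切れ": [
        "ヒューズが切断すること。",
        "過電流等によりヒューズが切れること",
    ],
    "バッテリ不良": [
        "バッテリ電圧・容量の低下",
        "バッテリの不良",
        "バッテリ自体の不良",
        "バッテリの異常でバッテリによる駆動ができないこと。",
    ],
    "緩み": [
        "ネジ、ロック等が緩むこと。",
        "ねじなどの締め付けが甘くなること。",
        "ネジ等が緩み、当該部位の物理的な保持・作用に支障をきたす状態の事",
        "構成部品の固着部 (ねじ、接着等) の結合力が弱まり、正常状態に比べて部品が動いてしまうこと",
        "接続不良となる接続部のがたつき。",
        "接続部分、固定などが緩むこと。",
        "装置又は器具の部分の固定が不良となること。",
        "通電不良となる接続部の固定力不足",
    ],
}
_TABLE5_PATIENT = {
    "感染症": [
        "ポケット部位から感染症となる。",
        "病原体が生体内に侵入し、一定の病変を惹起すること。",
    ],
    "心室細動": [
        "心室が整合的な収縮を行なわず、各部の筋肉が無秩序に収縮する状態",
        "心臓の心室が小刻みに震えて全身に血液を送ることができない状態。",
        "心室が規則に震えるように痙攣 (けいれん) する状態のこと。",
        "患者の心臓の拍動が小刻みな状態となって、拍出ができない状態。",
        "悪性の心室不整脈で、心室筋の持続的、非協調的な収縮によって特徴づけられ、心臓からの血流は途絶する。",
    ],
    "手術時間の延長": [
        "医療機器の不具合により当初予定していたよりも手術時間が長引いてしまうこと。",
        "医療機器の使用にともなう健康被害の発生に関連し、手術時間が長引いてしまうこと。",
    ],
    "虹彩脱出": [
        "眼球の穿孔部からの虹彩の一部が眼球外に脱出した状態。強角膜の穿孔性外傷や切開手術、"
        "または角膜軟化症・角膜炎が進行して角膜が穿孔したときに生じる。感染防止が重要で、"
        "速やかな虹彩整復手術を要する。",
        "眼球の穿孔部からの虹彩の一部が眼球外に脱出した状態",
        "虹彩が脱出すること。",
    ],
    "感染": [
        "病原微生物が人体に侵入し、臓器や組織中で増殖し、種々の症状をもたらすこと",
        "病原微生物が人体に侵入し、臓器や組織中で増殖し、種々の症状をもたらすこと。",
        "微生物が、体内に侵入・定着した状態。",
        "微生物が人体に侵入、増殖、何らの症状が出現する症例",
        "病原微生物または感染性物質が人体に侵入し、臓器や組織中で増殖し、種々の症状をもたらすこと",
        "微生物感染などによるもので、キズ口の周りが赤くなっていたり、ズキズキした痛みが続いたり、"
        "膿を持っていたり、熱や腫れ等の異常が認められる場合",
        "微生物が人体に侵入、増殖、何らの症状が出現する症例。",
        "微生物が、体内に侵入・定着した状態をいう。",
    ],
}

# preferred term -> all CDRH-NCIt targets ("Material deformation" /
# "material deformation" differ only in case and are distinct by default)
_TABLE6_DEVICE = {
    "ねじれ": ["Material twisted", "kinked"],
    "アラーム誤作動": ["Defective alarm", "improper alarm", "device alarm system issue"],
    "アラーム音不良": ["Device alarm system issue", "not audible alarm"],
    "変形": [
        "Lens aberration, distortion of",
        "material distortion",
        "Quality, unsatisfactory or poor",
        "Material deformation",
        "component(s), broken",
        "material deformation",
        "bend",
        "material integrity issue",
    ],
}
_TABLE6_PATIENT = {
    "巨大乳頭結膜炎": ["Foreign body reaction", "hypersensitivity", "conjunctivitis"],
    "湿疹": ["Rash", "skin inflammation"],
    "アレルギー反応": ["Hypersensitivity", "allergic reaction"],
    "穿孔": ["Vessels, perforation of", "cardiac perforation", "perforation", "injury"],
}

#: the eight labels used as hierarchy terms in both problem domains
TABLE7_TERMS = [
    "損傷", "汚染", "発熱", "感染", "感電", "その他の事象", "その他", "不明",
]


def _table2_sets() -> list[TerminologySet]:
    records = []
    for domain, rows in ((DEV, _TABLE2_DEVICE), (PAT, _TABLE2_PATIENT)):
        for cat, mid, pref in rows:
            records.append(_rec("T2A", domain, cat, mid))
            records.append(_rec("T2B", domain, mid, pref))
    return _sets(records)


# Scaffold category for preferred terms that also occur in other tables: reuse
# a parent already printed for them, so combining fixtures does not inflate
# parent multiplicities beyond the published numbers.
_SCAFFOLD_PARENT = {
    (DEV, "変形"): "故障",
    (DEV, "アーチファクト"): "異常画像",
    (DEV, "ヒューズ切れ"): "電気的不良",
    (DEV, "バッテリ不良"): "故障",
    (PAT, "アレルギー反応"): "感染",
}


def _scaffold_cat(domain, pref, fallback: str) -> str:
    return _SCAFFOLD_PARENT.get((domain, pref), fallback)


def _table3_sets() -> list[TerminologySet]:
    records = []
    counter = 0
    for domain, rows in ((DEV, _TABLE3_DEVICE), (PAT, _TABLE3_PATIENT)):
        for pref, mid, syn in rows:
            counter += 1
            records.append(
                _rec("T3A", domain, _scaffold_cat(domain, pref, f"T3C-{counter:02d}a"),
                     pref, syns=[mid])
            )
            records.append(_rec("T3B", domain, f"T3C-{counter:02d}b", mid, syns=[syn]))
    return _sets(records)


def _multiplicity_sets(
    tid_prefix: str, device_map: dict, patient_map: dict, kind: str
) -> list[TerminologySet]:
    records = []
    for domain, mapping in ((DEV, device_map), (PAT, patient_map)):
        dom_tag = "D" if domain is DEV else "P"
        for i, (pref, objects) in enumerate(mapping.items(), start=1):
            for m, obj in enumerate(objects):
                tid = f"{tid_prefix}{'A' if m % 2 == 0 else 'B'}"
                if kind == "parents":
                    records.append(_rec(tid, domain, obj, pref))
                elif kind == "definitions":
                    records.append(
                        _rec(tid, domain,
                             _scaffold_cat(domain, pref, f"{tid_prefix}C{dom_tag}-{i:02d}"),
                             pref, definition=obj)
                    )
                else:  # mappings: one record carries the whole target list
                    raise AssertionError("mappings handled separately")
    return _sets(records)


def _table6_sets() -> list[TerminologySet]:
    records = []
    for domain, mapping in ((DEV, _TABLE6_DEVICE), (PAT, _TABLE6_PATIENT)):
        dom_tag = "D" if domain is DEV else "P"
        for i, (pref, targets) in enumerate(mapping.items(), start=1):
            records.append(
                _rec("T6A", domain, _scaffold_cat(domain, pref, f"T6C{dom_tag}-{i:02d}"),
                     pref, ncit=targets)
            )
    return _sets(records)


def _table7_sets() -> list[TerminologySet]:
    records = []
    for i, term in enumerate(TABLE7_TERMS, start=1):
        records.append(_rec("T7A", DEV, f"T7CD-{i:02d}", term))
        records.append(_rec("T7B", PAT, f"T7CP-{i:02d}", term))
    # domain-unique distractors that must NOT be flagged
    records.append(_rec("T7A", DEV, "T7CD-90", "装置固有事象"))
    records.append(_rec("T7B", PAT, "T7CP-90", "患者固有事象"))
    # a label shared across domains only as a synonym: not a hierarchy term
    records.append(_rec("T7A", DEV, "T7CD-91", "装置側事象", syns=["共通別名"]))
    records.append(_rec("T7B", PAT, "T7CP-91", "患者側事象", syns=["共通別名"]))
    return _sets(records)


def table_fixtures() -> dict[str, list[TerminologySet]]:
    """Named worked-example fixtures, each a list of TerminologySets.

    Keys: table2 (dual-role hierarchy triples), table3 (preferred/synonym
    swaps), table4 / table4_deformation (polyhierarchy; 変形 has 11 category
    parents), table5 / table5_infection (multiple definitions; 感染 has 8),
    table6 / table6_perforation (multiple CDRH-NCIt mappings; 穿孔 has 4),
    table7 (the 8 cross-domain labels plus distractors).
    """
    table4 = _multiplicity_sets("T4", _TABLE4_DEVICE, _TABLE4_PATIENT, "parents")
    table5 = _multiplicity_sets("T5", _TABLE5_DEVICE, _TABLE5_PATIENT, "definitions")
    return {
        "table2": _table2_sets(),
        "table3": _table3_sets(),
        "table4": table4,
        "table4_deformation": _multiplicity_sets(
            "T4", {"変形": _TABLE4_DEVICE["変形"]}, {}, "parents"
        ),
        "table5": table5,
        "table5_infection": _multiplicity_sets(
            "T5", {}, {"感染": _TABLE5_PATIENT["感染"]}, "definitions"
        ),
        "table6": _table6_sets(),
        "table6_perforation": _sets(
            [_rec("T6A", PAT, "T6C-01", "穿孔", ncit=_TABLE6_PATIENT["穿孔"])]
        ),
        "table7": _table7_sets(),
    }


def all_fixture_sets() -> list[TerminologySet]:
    """Every fixture record in one list (terminology IDs are distinct per table)."""
    by_tid: dict[str, TerminologySet] = {}
    for name in ("table2", "table3", "table4", "table5", "table6", "table7"):
        for ts in table_fixtures()[name]:
            if ts.terminology_id in by_tid:
                by_tid[ts.terminology_id].records.extend(ts.records)
            else:
                by_tid[ts.terminology_id] = ts
    return [by_tid[tid] for tid in sorted(by_tid)]
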