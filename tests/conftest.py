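"""Shared fixtures: worked-example tables and random graph builders."""

from __future__ import annotations

import random

import pytest

from termaudit.fixtures import table_fixtures
from termaudit.graph import build_graph
from termaudit.records import ProblemDomain, TermRecord, TerminologySet


@pytest.fixture(scope="session")
def tables():
    return table_fixtures()


def make_record(
    tid="T1",
    domain=ProblemDomain.DEVICE,
    cat="カテゴリ",
    pref="用語",
    syns=(),
    definition="",
    ncit=(),
):
    return TermRecord(
        terminology_id=tid,
        problem_domain=domain,
        category_label=cat,
        preferred_label=pref,
        synonym_labels=list(syns),
        definition_text=definition,
        cdrh_ncit_labels=list(ncit),
    )


def make_set(tid, records):
    for rec in records:
        rec.terminology_id = tid
    return TerminologySet(terminology_id=tid, records=records)


def random_sets(seed: int, n_labels: int = 12, n_records: int = 25):
    """Random terminology sets over a small label pool, forcing collisions.

    Small pools make dual roles, swaps, polyhierarchy and cycles frequent,
    which is what the brute-force oracle comparisons need.
    """
    rng = random.Random(seed)
    labels = [f"L{i:02d}" for i in range(n_labels)]
    defs = [f"def {i}" for i in range(4)]
    ncits = [f"NC{i}" for i in range(4)]
    tids = ["A01", "B02", "C03"]
    sets: dict[str, TerminologySet] = {}
    for _ in range(n_records):
        tid = rng.choice(tids)
        domain = rng.choice([ProblemDomain.DEVICE, ProblemDomain.PATIENT])
        pref = rng.choice(labels)
        rec = make_record(
            tid=tid,
            domain=domain,
            cat=rng.choice(labels),
            pref=pref,
            syns=rng.sample([l for l in labels if l != pref], rng.randint(0, 2)),
            definition=rng.choice(defs) if rng.random() < 0.7 else "",
            ncit=rng.sample(ncits, rng.randint(0, 2)),
        )
        sets.setdefault(tid, TerminologySet(terminology_id=tid)).records.append(rec)
    return list(sets.values())


def random_graph(seed: int, domain=ProblemDomain.DEVICE, **kwargs):
    return build_graph(random_sets(seed, **kwargs), domain)
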