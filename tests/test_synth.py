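"""Synthetic generator: determinism, feasibility, exact planted recovery."""

import io

import pytest

from termaudit import (
    ConfigError,
    ProblemDomain,
    SynthConfig,
    build_graph,
    generate_terminologies,
    run_all_checks,
)
from termaudit.checks import (
    CROSS_DOMAIN,
    CYCLE,
    DUAL_ROLE,
    MULTI_DEFINITION,
    MULTI_MAPPING,
    MULTI_PARENT,
    SWAP,
)
from termaudit.tabular import write_terminology_table

SMALL = dict(n_terminologies=4, n_categories_per_set=3, n_preferred_per_category=2)


def _serialize(sets) -> str:
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "t.csv"
        write_terminology_table(sets, path)
        return path.read_text(encoding="utf-8")


def assert_matches_bookkeeping(sets, bookkeeping):
    dev = build_graph(sets, ProblemDomain.DEVICE)
    pat = build_graph(sets, ProblemDomain.PATIENT)
    results = run_all_checks(dev, pat)
    for cid in (DUAL_ROLE, SWAP, MULTI_PARENT, MULTI_DEFINITION, MULTI_MAPPING):
        for dom in ("device", "patient"):
            r = results[cid][dom]
            expected = bookkeeping.expected[cid][dom]
            assert r.pattern_count == expected["pattern_count"], (cid, dom)
            assert r.unique_term_count == expected["unique_term_count"], (cid, dom)
            assert r.max_multiplicity == expected["max_multiplicity"], (cid, dom)
    r6 = results[CROSS_DOMAIN]
    assert r6.pattern_count == bookkeeping.expected[CROSS_DOMAIN]["pattern_count"]
    for dom in ("device", "patient"):
        got = [f.pattern for f in results[CYCLE][dom].findings]
        assert got == list(bookkeeping.expected_cycles[dom]), dom


def test_same_seed_gives_byte_identical_output():
    cfg = SynthConfig(seed=11, dual_role=2, swaps=1, cycle_lengths=[2], **SMALL)
    a, _ = generate_terminologies(cfg)
    b, _ = generate_terminologies(SynthConfig(seed=11, dual_role=2, swaps=1,
                                              cycle_lengths=[2], **SMALL))
    assert _serialize(a) == _serialize(b)


def test_different_seed_changes_background_sampling():
    a, _ = generate_terminologies(SynthConfig(seed=1, **SMALL))
    b, _ = generate_terminologies(SynthConfig(seed=2, **SMALL))
    assert _serialize(a) != _serialize(b)


def test_all_zero_planting_yields_all_empty_checks():
    sets, bookkeeping = generate_terminologies(SynthConfig(seed=5, **SMALL))
    dev = build_graph(sets, ProblemDomain.DEVICE)
    pat = build_graph(sets, ProblemDomain.PATIENT)
    results = run_all_checks(dev, pat)
    for cid in (DUAL_ROLE, SWAP, MULTI_PARENT, MULTI_DEFINITION, MULTI_MAPPING):
        for dom in ("device", "patient"):
            assert results[cid][dom].pattern_count == 0
    assert results[CROSS_DOMAIN].pattern_count == 0
    assert_matches_bookkeeping(sets, bookkeeping)


def test_planted_dual_role_count_recovered():
    sets, bookkeeping = generate_terminologies(
        SynthConfig(seed=7, dual_role=5, **SMALL)
    )
    assert bookkeeping.expected[DUAL_ROLE]["device"]["unique_term_count"] == 5
    assert_matches_bookkeeping(sets, bookkeeping)


def test_planted_definition_multiplicity_recovered():
    sets, bookkeeping = generate_terminologies(
        SynthConfig(seed=7, multi_definition=3, multi_definition_multiplicity=8, **SMALL)
    )
    assert bookkeeping.expected[MULTI_DEFINITION]["device"]["max_multiplicity"] == 8
    assert_matches_bookkeeping(sets, bookkeeping)


def test_cycles_also_count_as_dual_role_patterns():
    sets, bookkeeping = generate_terminologies(
        SynthConfig(seed=9, dual_role=1, cycle_lengths=[1, 2, 3], **SMALL)
    )
    assert bookkeeping.expected[DUAL_ROLE]["device"]["pattern_count"] == 1 + 6
    assert_matches_bookkeeping(sets, bookkeeping)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(dual_role=-1),
        dict(duplication_factor=0.5),
        dict(multi_parent=1, multi_parent_multiplicity=1),
        dict(multi_mapping=2, multi_mapping_multiplicity=0),
        dict(cycle_lengths=[0]),
    ],
)
def test_infeasible_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        generate_terminologies(SynthConfig(seed=0, **SMALL, **kwargs))


def test_background_duplication_reduces_terms():
    from termaudit import count_terms, per_terminology_term_counts

    sets, _ = generate_terminologies(
        SynthConfig(seed=3, n_terminologies=30, n_categories_per_set=6,
                    n_preferred_per_category=3, duplication_factor=2.5)
    )
    g = build_graph(sets, ProblemDomain.DEVICE)
    pre = sum(tc.combined for tc in per_terminology_term_counts(g).values())
    post = count_terms(g).combined
    assert post < pre
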