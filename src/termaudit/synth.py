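"""Synthetic terminology generator with planted, countable inconsistencies.

Emulates the shape of the published adverse-event terminology release: many
per-device-group sets, each with a medical-device-problem and a
patient-problem section, a two-level category/preferred hierarchy, and
synonyms, a definition and a CDRH-NCIt mapping per preferred term.
Different sets share whole records (industry associations reused terms
across similar device groups), so notation-based integration deduplicates
substantially.

Planted inconsistencies are built from vocabulary pools disjoint from the
background vocabulary and from each other, so every planted structure
triggers exactly one audit check and the expected counts can be stated
exactly. The one unavoidable overlap is planted hierarchy cycles: any cycle
makes each of its labels both a category and a preferred term, so each
planted cycle of length L also contributes L dual-role patterns; the
bookkeeping accounts for this explicitly.

Labels are opaque synthetic tokens, not real medical terms, so accidental
collisions cannot perturb the planted counts. Generation is a pure function
of the config: the same seed yields identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .checks import (
    CROSS_DOMAIN,
    CYCLE,
    DUAL_ROLE,
    MULTI_DEFINITION,
    MULTI_MAPPING,
    MULTI_PARENT,
    SWAP,
)
from .records import ProblemDomain, TermRecord, TerminologySet


class ConfigError(ValueError):
    """The synthesis config is internally inconsistent or infeasible."""


@dataclass
class SynthConfig:
    """Generator parameters.

    Background shape defaults mirror the published release: 89 terminology
    sets; per set and domain roughly 11 categories with ~3 preferred terms
    each (89 × ~38 ≈ 3400 preferred-term rows per domain before
    integration) and about one synonym per preferred term.
    ``duplication_factor`` controls how many sets share each background
    record (2.5 gives the observed ~60% duplicate removal). Planted counts
    all default to zero: planting is an explicit test-design act.
    """

    seed: int = 0
    n_terminologies: int = 89
    n_categories_per_set: int = 11
    n_preferred_per_category: int = 3
    n_synonyms_per_preferred: int = 1
    duplication_factor: float = 2.5
    dual_role: int = 0
    swaps: int = 0
    multi_parent: int = 0
    multi_parent_multiplicity: int = 2
    multi_definition: int = 0
    multi_definition_multiplicity: int = 2
    multi_mapping: int = 0
    multi_mapping_multiplicity: int = 2
    cross_domain: int = 0
    cycle_lengths: list[int] = field(default_factory=list)

    def validate(self) -> None:
        counts = {
            "n_terminologies": self.n_terminologies,
            "n_categories_per_set": self.n_categories_per_set,
            "n_preferred_per_category": self.n_preferred_per_category,
            "n_synonyms_per_preferred": self.n_synonyms_per_preferred,
            "dual_role": self.dual_role,
            "swaps": self.swaps,
            "multi_parent": self.multi_parent,
            "multi_definition": self.multi_definition,
            "multi_mapping": self.multi_mapping,
            "cross_domain": self.cross_domain,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.duplication_factor < 1:
            raise ConfigError("duplication_factor must be >= 1")
        for name, count, mult in (
            ("multi_parent", self.multi_parent, self.multi_parent_multiplicity),
            ("multi_definition", self.multi_definition, self.multi_definition_multiplicity),
            ("multi_mapping", self.multi_mapping, self.multi_mapping_multiplicity),
        ):
            if count > 0 and mult < 2:
                raise ConfigError(f"{name}_multiplicity must be >= 2, got {mult}")
        for length in self.cycle_lengths:
            if length < 1:
                raise ConfigError(f"cycle lengths must be >= 1, got {length}")


@dataclass
class Bookkeeping:
    """Expected audit outcome for a generated dataset.

    ``expected[check_id][domain]`` holds pattern_count / unique_term_count /
    max_multiplicity; ``expected_cycles[domain]`` lists the planted cycles
    in canonical rotation. run_all_checks on the generated data must match
    exactly.
    """

    expected: dict = field(default_factory=dict)
    expected_cycles: dict = field(default_factory=dict)


def _zero() -> dict:
    return {"pattern_count": 0, "unique_term_count": 0, "max_multiplicity": None}


def _background_records(
    config: SynthConfig, domain: ProblemDomain, rng: random.Random
) -> dict[int, list[tuple]]:
    """Per-terminology background record templates (device/patient pools disjoint)."""
    prefix = "D" if domain is ProblemDomain.DEVICE else "P"
    total_cats = config.n_terminologies * config.n_categories_per_set
    n_global = max(
        config.n_categories_per_set, round(total_cats / config.duplication_factor)
    )
    if total_cats == 0:
        return {i: [] for i in range(config.n_terminologies)}

    def records_for_category(c: int) -> list[tuple]:
        cat = f"{prefix}-CAT{c:05d}"
        out = []
        for j in range(config.n_preferred_per_category):
            pref = f"{prefix}-PT{c:05d}-{j:02d}"
            syns = [
                f"{prefix}-SYN{c:05d}-{j:02d}-{k:02d}"
                for k in range(config.n_synonyms_per_preferred)
            ]
            out.append(
                (cat, pref, syns, f"{pref} standard definition.", [f"NC {pref}"])
            )
        return out

    per_set: dict[int, list[tuple]] = {}
    for i in range(config.n_terminologies):
        chosen = rng.sample(range(n_global), min(config.n_categories_per_set, n_global))
        recs: list[tuple] = []
        for c in sorted(chosen):
            recs.extend(records_for_category(c))
        per_set[i] = recs
    return per_set


def generate_terminologies(
    config: SynthConfig,
) -> tuple[list[TerminologySet], Bookkeeping]:
    """Generate terminology sets plus the exact expected audit counts.

    Background records go into sets S000…; planted records go into two
    dedicated sets (PLA, PLB) so each planted pattern has cross-set
    provenance, as real inconsistencies do. Raises ConfigError for an
    infeasible config.
    """
    config.validate()
    rng = random.Random(config.seed)

    sets: dict[str, TerminologySet] = {}

    def add(tid: str, domain: ProblemDomain, cat: str, pref: str,
            syns: list[str] | None = None, definition: str | None = None,
            ncit: list[str] | None = None) -> None:
        if tid not in sets:
            sets[tid] = TerminologySet(terminology_id=tid,
                                       device_group_name=f"synthetic group {tid}")
        sets[tid].records.append(
            TermRecord(
                terminology_id=tid,
                problem_domain=domain,
                category_label=cat,
                preferred_label=pref,
                synonym_labels=list(syns or []),
                definition_text=(definition if definition is not None
                                 else f"{pref} standard definition."),
                cdrh_ncit_labels=list(ncit if ncit is not None else [f"NC {pref}"]),
            )
        )

    for domain in (ProblemDomain.DEVICE, ProblemDomain.PATIENT):
        per_set = _background_records(config, domain, rng)
        for i, recs in per_set.items():
            tid = f"S{i:03d}"
            for cat, pref, syns, definition, ncit in recs:
                add(tid, domain, cat, pref, syns, definition, ncit)

    dev = ProblemDomain.DEVICE
    pat = ProblemDomain.PATIENT

    # check 1: dual-role terms (parent and child live in different sets)
    for i in range(config.dual_role):
        term = f"DR{i:04d}"
        add("PLA", dev, f"DRP{i:04d}", term)
        add("PLB", dev, term, f"DRC{i:04d}")

    # check 2: preferred/synonym swaps
    for i in range(config.swaps):
        p, x = f"SWP{i:04d}", f"SWX{i:04d}"
        add("PLA", dev, f"SWC{i:04d}-a", p, syns=[x])
        add("PLB", dev, f"SWC{i:04d}-b", x, syns=[p])

    # check 3: preferred terms with several category parents
    for i in range(config.multi_parent):
        pref = f"MP{i:04d}"
        for m in range(config.multi_parent_multiplicity):
            add("PLA" if m % 2 == 0 else "PLB", dev, f"MPC{i:04d}-{m:02d}", pref)

    # check 4: preferred terms with several distinct definitions
    for i in range(config.multi_definition):
        pref = f"MD{i:04d}"
        for m in range(config.multi_definition_multiplicity):
            add("PLA" if m % 2 == 0 else "PLB", dev, f"MDC{i:04d}", pref,
                definition=f"{pref} definition variant {m}.")

    # check 5: preferred terms mapped to several CDRH-NCIt terms
    for i in range(config.multi_mapping):
        pref = f"MM{i:04d}"
        add("PLA", dev, f"MMC{i:04d}", pref,
            ncit=[f"NC {pref} v{m}" for m in range(config.multi_mapping_multiplicity)])

    # check 6: hierarchy labels shared between the two domains
    for i in range(config.cross_domain):
        term = f"XD{i:04d}"
        add("PLA", dev, f"XDC{i:04d}-d", term)
        add("PLB", pat, f"XDC{i:04d}-p", term)

    # planted cycles in the device subclass relation (child -> parent)
    expected_cycles: list[tuple[str, ...]] = []
    for ci, length in enumerate(config.cycle_lengths):
        labels = [f"CY{ci:03d}-{k:02d}" for k in range(length)]
        for k in range(length):
            add("PLA" if k % 2 == 0 else "PLB", dev,
                labels[(k + 1) % length], labels[k])
        expected_cycles.append(tuple(labels))

    cycle_dual_patterns = sum(config.cycle_lengths)
    expected = {
        DUAL_ROLE: {
            "device": {
                "pattern_count": config.dual_role + cycle_dual_patterns,
                "unique_term_count": config.dual_role + cycle_dual_patterns,
                "max_multiplicity": None,
            },
            "patient": _zero(),
        },
        SWAP: {
            "device": {
                "pattern_count": 2 * config.swaps,
                "unique_term_count": 2 * config.swaps,
                "max_multiplicity": None,
            },
            "patient": _zero(),
        },
        MULTI_PARENT: {
            "device": {
                "pattern_count": config.multi_parent,
                "unique_term_count": config.multi_parent,
                "max_multiplicity": (
                    config.multi_parent_multiplicity if config.multi_parent else None
                ),
            },
            "patient": _zero(),
        },
        MULTI_DEFINITION: {
            "device": {
                "pattern_count": config.multi_definition,
                "unique_term_count": config.multi_definition,
                "max_multiplicity": (
                    config.multi_definition_multiplicity
                    if config.multi_definition
                    else None
                ),
            },
            "patient": _zero(),
        },
        MULTI_MAPPING: {
            "device": {
                "pattern_count": config.multi_mapping,
                "unique_term_count": config.multi_mapping,
                "max_multiplicity": (
                    config.multi_mapping_multiplicity if config.multi_mapping else None
                ),
            },
            "patient": _zero(),
        },
        CROSS_DOMAIN: {
            "pattern_count": config.cross_domain,
            "unique_term_count": config.cross_domain,
            "max_multiplicity": None,
        },
    }
    bookkeeping = Bookkeeping(
        expected=expected,
        # lexicographic by pattern, matching the checks' finding order
        expected_cycles={"device": sorted(expected_cycles), "patient": []},
    )
    return [sets[tid] for tid in sorted(sets)], bookkeeping
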