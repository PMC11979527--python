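"""Shared fixtures: tiny handcrafted collections and one benchmark run.

The benchmark run (200k simulated reports, seed 1) is expensive enough to
share session-wide; every test that needs it reads from the same frozen
result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import tdpddi as t


def make_report(rid, drugs, pts=(), reporter="physician", sex="female",
                age=50.0, country="united states", outcomes=("other",)):
    """Compact report builder: ``drugs`` is a list of (name, role) or names."""
    entries = []
    for item in drugs:
        name, role = item if isinstance(item, tuple) else (item, "C")
        entries.append(t.DrugEntry(name, frozenset({role})))
    return t.Report(
        report_id=rid,
        drugs=tuple(entries),
        pts=frozenset(pts),
        reporter_type=reporter,
        sex=sex,
        age_years=age,
        country=country,
        outcomes=frozenset(outcomes),
    )


TARGET = "10044066"


@pytest.fixture
def four_cell_collection():
    """One report per 2x2 cell for a single drug vs the event."""
    return t.ReportCollection(
        [
            make_report("r1", ["amiodarone"], pts=[TARGET]),
            make_report("r2", ["amiodarone"], pts=["10000001"]),
            make_report("r3", ["sotalol"], pts=[TARGET]),
            make_report("r4", ["sotalol"], pts=["10000001"]),
        ]
    )


def random_collection(rng, n_reports=200, n_drugs=30, exposure=0.12, event=0.2):
    """Random reports for brute-force comparisons (no structure, no truth)."""
    names = [f"drug{i:02d}" for i in range(n_drugs)]
    reports = []
    for i in range(n_reports):
        exposed = [names[j] for j in range(n_drugs) if rng.random() < exposure]
        pts = {TARGET} if rng.random() < event else {"10000001"}
        reports.append(make_report(f"r{i:04d}", exposed, pts=pts))
    return t.ReportCollection(reports)


@dataclass
class BenchmarkRun:
    config: "t.SyntheticConfig"
    collection: "t.ReportCollection"
    case_flags: np.ndarray
    pairs: list
    signals: "object"
    synergy: set
    no_synergy: set
    negative_control: tuple


@pytest.fixture(scope="session")
def benchmark_run() -> BenchmarkRun:
    config = t.benchmark_default()
    collection = t.generate_reports(config, seed=1)
    flags = t.mark_cases(collection, config.target_pt)
    pairs = t.eligible_pairs(
        collection, flags, min_cases=3, min_drug_cases=3
    )
    signals = t.run_all_models(pairs, min_cases=3)
    return BenchmarkRun(
        config=config,
        collection=collection,
        case_flags=flags,
        pairs=pairs,
        signals=signals,
        synergy=set(t.ground_truth(config)),
        no_synergy=set(t.no_synergy_pairs(config)),
        negative_control=t.benchmark_negative_control(config),
    )
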