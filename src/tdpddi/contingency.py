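"""Contingency tables for disproportionality analysis.

Two tables underlie everything: the single-drug 2x2 table (a, b, c, d) used
by the reporting odds ratio, and the drug-pair 4x2 table n_ijk, where i and
j index exposure to the two drugs and k the occurrence of the target event.
Pair enumeration streams over reports and keeps sparse per-pair counters;
no dense drugs-by-drugs matrix is ever materialized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .reports import ReportCollection, normalize_drug_name


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Canonical unordered-pair key: normalized names, lexicographically sorted."""
    a = normalize_drug_name(drug_a)
    b = normalize_drug_name(drug_b)
    if not a or not b:
        raise ValueError("drug names must be non-empty")
    if a == b:
        raise ValueError(f"a pair needs two distinct drugs, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True, slots=True)
class SingleDrugCounts:
    """2x2 table for one drug vs the event.

    a: drug & event, b: drug only, c: event only, d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class PairCounts:
    """4x2 table for a drug pair vs the event.

    ``n_ijk``: i = exposure to the first drug of the canonical pair,
    j = exposure to the second, k = event (1) or no event (0).
    """

    n111: int
    n110: int
    n101: int
    n100: int
    n011: int
    n010: int
    n001: int
    n000: int

    @property
    def n11p(self) -> int:
        return self.n111 + self.n110

    @property
    def n10p(self) -> int:
        return self.n101 + self.n100

    @property
    def n01p(self) -> int:
        return self.n011 + self.n010

    @property
    def n00p(self) -> int:
        return self.n001 + self.n000

    @property
    def n(self) -> int:
        return self.n11p + self.n10p + self.n01p + self.n00p

    @property
    def n_cases(self) -> int:
        return self.n111 + self.n101 + self.n011 + self.n001

    def swapped(self) -> "PairCounts":
        """The same table with the two drugs' indices exchanged."""
        return PairCounts(
            n111=self.n111,
            n110=self.n110,
            n101=self.n011,
            n100=self.n010,
            n011=self.n101,
            n010=self.n100,
            n001=self.n001,
            n000=self.n000,
        )


def _check_alignment(collection: ReportCollection, case_flags: np.ndarray) -> np.ndarray:
    flags = np.asarray(case_flags, dtype=bool)
    if flags.shape != (collection.n_total,):
        raise ValueError("case_flags must align with the collection")
    return flags


def single_drug_counts(
    collection: ReportCollection, case_flags: np.ndarray, drug: str
) -> SingleDrugCounts:
    """Count the 2x2 drug-vs-event table over deduplicated per-report drug sets."""
    name = normalize_drug_name(drug)
    if not name:
        raise ValueError("drug name must be non-empty")
    flags = _check_alignment(collection, case_flags)
    a = b = c = d = 0
    for report, is_case in zip(collection.reports, flags):
        exposed = name in report.drug_names
        if exposed and is_case:
            a += 1
        elif exposed:
            b += 1
        elif is_case:
            c += 1
        else:
            d += 1
    return SingleDrugCounts(a, b, c, d)


def pair_counts(
    collection: ReportCollection,
    case_flags: np.ndarray,
    drug_a: str,
    drug_b: str,
) -> PairCounts:
    """Count the 4x2 table for one drug pair (canonical orientation)."""
    low, high = canonical_pair(drug_a, drug_b)
    flags = _check_alignment(collection, case_flags)
    cells = Counter()
    for report, is_case in zip(collection.reports, flags):
        names = report.drug_names
        i = int(low in names)
        j = int(high in names)
        cells[(i, j, int(is_case))] += 1
    return PairCounts(
        n111=cells[(1, 1, 1)],
        n110=cells[(1, 1, 0)],
        n101=cells[(1, 0, 1)],
        n100=cells[(1, 0, 0)],
        n011=cells[(0, 1, 1)],
        n010=cells[(0, 1, 0)],
        n001=cells[(0, 0, 1)],
        n000=cells[(0, 0, 0)],
    )


def eligible_pairs(
    collection: ReportCollection,
    case_flags: np.ndarray,
    min_cases: int = 3,
    min_drug_cases: int = 3,
) -> list[tuple[tuple[str, str], PairCounts]]:
    """Enumerate drug pairs with at least ``min_cases`` co-exposed case reports.

    Candidate drugs must themselves appear in at least ``min_drug_cases``
    case reports (the drug-level screen applied before pairing).  The scan
    is two-pass: case reports first (candidate pairs and their n111), then
    all reports for the remaining margins.  Output is sorted by pair key.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    flags = _check_alignment(collection, case_flags)

    drug_case_counts: Counter[str] = Counter()
    case_drug_sets: list[frozenset[str]] = []
    for report, is_case in zip(collection.reports, flags):
        if is_case:
            names = report.drug_names
            case_drug_sets.append(names)
            drug_case_counts.update(names)
    screened = {d for d, k in drug_case_counts.items() if k >= min_drug_cases}

    cc: Counter[tuple[str, str]] = Counter()  # co-exposed case reports per pair
    for names in case_drug_sets:
        rel = sorted(names & screened)
        for pair in combinations(rel, 2):
            cc[pair] += 1
    kept = {pair for pair, k in cc.items() if k >= min_cases}
    if not kept:
        return []

    relevant = {d for pair in kept for d in pair}
    n_total = collection.n_total
    n_cases = int(flags.sum())
    drug_totals: Counter[str] = Counter()  # reports listing the drug
    drug_cases: Counter[str] = Counter()  # case reports listing the drug
    co: Counter[tuple[str, str]] = Counter()  # reports listing both drugs
    for report, is_case in zip(collection.reports, flags):
        rel = sorted(report.drug_names & relevant)
        if not rel:
            continue
        drug_totals.update(rel)
        if is_case:
            drug_cases.update(rel)
        for pair in combinations(rel, 2):
            if pair in kept:
                co[pair] += 1

    out: list[tuple[tuple[str, str], PairCounts]] = []
    for pair in sorted(kept):
        low, high = pair
        n111 = cc[pair]
        n11p = co[pair]
        n101 = drug_cases[low] - n111
        n10p = drug_totals[low] - n11p
        n011 = drug_cases[high] - n111
        n01p = drug_totals[high] - n11p
        n001 = n_cases - drug_cases[low] - drug_cases[high] + n111
        n00p = n_total - drug_totals[low] - drug_totals[high] + n11p
        out.append(
            (
                pair,
                PairCounts(
                    n111=n111,
                    n110=n11p - n111,
                    n101=n101,
                    n100=n10p - n101,
                    n011=n011,
                    n010=n01p - n011,
                    n001=n001,
                    n000=n00p - n001,
                ),
            )
        )
    return out


def pairs_to_frame(pairs: Sequence[tuple[tuple[str, str], PairCounts]]):
    """Long-form table of pair keys, the eight cells and stratum margins."""
    import pandas as pd

    rows = []
    for (low, high), pc in pairs:
        rows.append(
            {
                "drug1": low,
                "drug2": high,
                "n111": pc.n111,
                "n110": pc.n110,
                "n101": pc.n101,
                "n100": pc.n100,
                "n011": pc.n011,
                "n010": pc.n010,
                "n001": pc.n001,
                "n000": pc.n000,
                "n11+": pc.n11p,
                "n10+": pc.n10p,
                "n01+": pc.n01p,
                "n00+": pc.n00p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug1", "drug2", "n111", "n110", "n101", "n100",
            "n011", "n010", "n001", "n000", "n11+", "n10+", "n01+", "n00+",
        ],
    )


def frame_to_pairs(df) -> list[tuple[tuple[str, str], PairCounts]]:
    """Inverse of :func:`pairs_to_frame` (margins are recomputed, not trusted)."""
    out = []
    for row in df.itertuples(index=False):
        pair = canonical_pair(str(row.drug1), str(row.drug2))
        out.append(
            (
                pair,
                PairCounts(
                    n111=int(row.n111),
                    n110=int(row.n110),
                    n101=int(row.n101),
                    n100=int(row.n100),
                    n011=int(row.n011),
                    n010=int(row.n010),
                    n001=int(row.n001),
                    n000=int(row.n000),
                ),
            )
        )
    return sorted(out, key=lambda item: item[0])
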