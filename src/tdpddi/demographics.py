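"""Demographic summary of the target-event cases.

Produces the case-characteristics table: sex, age band, severity outcome,
reporter type and reporter country, each with count and percentage of total
cases, plus two derived rows (cases older than 60; nonprofessional
reporters = consumer + lawyer).  A case contributes one category per
dimension; multiple recorded outcomes collapse to the most severe.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .reports import NONPROFESSIONAL_REPORTERS, ReportCollection

AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("0-19", 0, 20),
    ("20-39", 20, 40),
    ("40-59", 40, 60),
    ("60-79", 60, 80),
    (">=80", 80, float("inf")),
)

# Worst-first severity hierarchy; one category per case.
SEVERITY_ORDER: tuple[str, ...] = (
    "death",
    "life_threatening",
    "disability",
    "hospitalization",
    "required_intervention",
    "other",
    "unknown",
)


def percentage(count: int, total: int) -> float:
    """Share of ``total`` as a percentage, rounded half-up to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    value = Decimal(count * 100) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def age_band(age_years: float | None) -> str:
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    for label, low, high in AGE_BANDS:
        if low <= age_years < high:
            return label
    return "unknown"


def severity_category(outcomes: frozenset[str]) -> str:
    for category in SEVERITY_ORDER:
        if category in outcomes:
            return category
    return "unknown"


def summarize_demographics(
    collection: ReportCollection, case_flags: np.ndarray
) -> pd.DataFrame:
    """Case-characteristics table with counts and percentages of total cases."""
    flags = np.asarray(case_flags, dtype=bool)
    if flags.shape != (collection.n_total,):
        raise ValueError("case_flags must align with the collection")
    cases = [r for r, f in zip(collection.reports, flags) if f]
    total = len(cases)
    if total == 0:
        raise ValueError("no cases: cannot summarize demographics")

    def tally(dimension: str, values: list[str], order: list[str]) -> list[dict]:
        counts = pd.Series(values).value_counts()
        seen = [v for v in order if v in counts.index]
        seen += [v for v in counts.index if v not in order]
        return [
            {
                "dimension": dimension,
                "category": v,
                "count": int(counts[v]),
                "pct": percentage(int(counts[v]), total),
            }
            for v in seen
        ]

    rows: list[dict] = []
    rows += tally("sex", [c.sex for c in cases], ["male", "female", "unknown"])
    band_order = [b[0] for b in AGE_BANDS] + ["unknown"]
    bands = [age_band(c.age_years) for c in cases]
    rows += tally("age_band", bands, band_order)
    rows += tally(
        "severity", [severity_category(c.outcomes) for c in cases], list(SEVERITY_ORDER)
    )
    rows += tally(
        "reporter",
        [c.reporter_type for c in cases],
        [
            "other_health_professional",
            "physician",
            "pharmacist",
            "unknown",
            "consumer",
            "lawyer",
        ],
    )
    rows += tally("country", [c.country for c in cases], [])

    older = sum(1 for b in bands if b in {"60-79", ">=80"})
    nonprof = sum(1 for c in cases if c.reporter_type in NONPROFESSIONAL_REPORTERS)
    rows.append(
        {
            "dimension": "derived",
            "category": "older_than_60",
            "count": older,
            "pct": percentage(older, total),
        }
    )
    rows.append(
        {
            "dimension": "derived",
            "category": "nonprofessional",
            "count": nonprof,
            "pct": percentage(nonprof, total),
        }
    )
    rows.append(
        {"dimension": "total", "category": "cases", "count": total, "pct": 100.0}
    )
    return pd.DataFrame(rows, columns=["dimension", "category", "count", "pct"])
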