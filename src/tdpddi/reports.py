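"""Case-level spontaneous adverse-event reports: model, IO, filtering.

A report carries the drugs given to one patient (each with a FAERS-style
role code: primary suspect PS, secondary suspect SS, concomitant C,
interacting I), the adverse events coded as MedDRA preferred terms (PTs,
treated as opaque strings), and report-level demographics.  All downstream
counting is based on the *deduplicated* set of drug names within a report:
a drug listed under several roles in one report counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_CODES: tuple[str, ...] = ("PS", "SS", "C", "I")

REPORTER_TYPES: tuple[str, ...] = (
    "physician",
    "pharmacist",
    "other_health_professional",
    "consumer",
    "lawyer",
    "unknown",
)

NONPROFESSIONAL_REPORTERS: frozenset[str] = frozenset({"consumer", "lawyer"})

SEXES: tuple[str, ...] = ("male", "female", "unknown")

OUTCOMES: tuple[str, ...] = (
    "death",
    "life_threatening",
    "disability",
    "hospitalization",
    "required_intervention",
    "other",
    "unknown",
)

# FAERS-flavoured aliases accepted on input; everything else maps to unknown.
_REPORTER_ALIASES: dict[str, str] = {
    "md": "physician",
    "physician": "physician",
    "medical doctor": "physician",
    "ph": "pharmacist",
    "pharmacist": "pharmacist",
    "ot": "other_health_professional",
    "hp": "other_health_professional",
    "rn": "other_health_professional",
    "other health professional": "other_health_professional",
    "other_health_professional": "other_health_professional",
    "health professional": "other_health_professional",
    "cn": "consumer",
    "consumer": "consumer",
    "lw": "lawyer",
    "lawyer": "lawyer",
}

_SEX_ALIASES: dict[str, str] = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}

_OUTCOME_ALIASES: dict[str, str] = {
    "de": "death",
    "death": "death",
    "died": "death",
    "lt": "life_threatening",
    "life_threatening": "life_threatening",
    "life threatening": "life_threatening",
    "ds": "disability",
    "disability": "disability",
    "disabled": "disability",
    "ho": "hospitalization",
    "hospitalization": "hospitalization",
    "hospitalized": "hospitalization",
    "ri": "required_intervention",
    "required_intervention": "required_intervention",
    "ot": "other",
    "other": "other",
}


class SchemaError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


class RowError(ValueError):
    """A row-level value cannot be validated (carries the report id)."""


def normalize_drug_name(name: str) -> str:
    """Trim and case-fold a drug label.

    Trade-name to generic mapping is deliberately not attempted; an
    optional synonym table can be supplied to :func:`read_reports`.
    """
    return str(name).strip().casefold()


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug within a report, with every role code it was listed under."""

    name: str
    roles: frozenset[str] = frozenset({"C"})

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("drug name is empty after normalization")
        bad = set(self.roles) - set(ROLE_CODES)
        if bad:
            raise ValueError(f"unknown role codes: {sorted(bad)}")


@dataclass(frozen=True, slots=True)
class Report:
    """One spontaneous report (one case)."""

    report_id: str
    drugs: tuple[DrugEntry, ...]
    pts: frozenset[str]
    reporter_type: str = "unknown"
    sex: str = "unknown"
    age_years: float | None = None
    country: str = "unknown"
    outcomes: frozenset[str] = frozenset()

    @property
    def drug_names(self) -> frozenset[str]:
        return frozenset(e.name for e in self.drugs)

    def drugs_with_roles(self, roles: Iterable[str]) -> frozenset[str]:
        keep = frozenset(roles)
        return frozenset(e.name for e in self.drugs if e.roles & keep)


@dataclass(slots=True)
class ReportCollection:
    """An ordered collection of reports with unique ids."""

    reports: list[Report] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate report_id in collection")

    @property
    def n_total(self) -> int:
        return len(self.reports)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


FLAT_COLUMNS = (
    "report_id",
    "drug_name",
    "role_code",
    "pt_code",
    "reporter_type",
    "sex",
    "age",
    "country",
    "outcome",
)


def _canon_categorical(raw: object, aliases: Mapping[str, str]) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    key = str(raw).strip().casefold()
    if not key or key in {"nan", "unknown", "not obtained", "na"}:
        return "unknown"
    return aliases.get(key, "unknown")


def _parse_age(raw: object) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if not text or text.casefold() in {"nan", "unknown", "na"}:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    return value if value >= 0 else None


def _split_multi(raw: object) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    return [p.strip() for p in str(raw).split(";") if p.strip() and p.strip().casefold() != "nan"]


def _read_delimited(path: Path) -> pd.DataFrame:
    # Tab or comma, auto-detected from the header line.
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])


def _require_columns(df: pd.DataFrame, needed: Sequence[str], what: str) -> None:
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


def _build_reports(
    rows: pd.DataFrame,
    synonyms: Mapping[str, str] | None,
) -> list[Report]:
    """Assemble reports from a long table with one row per report-drug."""
    reports: list[Report] = []
    for report_id, grp in rows.groupby("report_id", sort=True):
        demo_cols = ["reporter_type", "sex", "age", "country"]
        demo = grp[demo_cols].drop_duplicates()
        if len(demo) > 1:
            raise RowError(
                f"report {report_id!r}: conflicting demographics across rows"
            )
        roles_by_drug: dict[str, set[str]] = {}
        for _, row in grp.iterrows():
            raw_name = row["drug_name"]
            name = normalize_drug_name(raw_name)
            if synonyms and name in synonyms:
                name = synonyms[name]
            if not name:
                if str(raw_name).strip() == "" and not str(row["role_code"]).strip():
                    continue  # fully blank drug slot (report with no drugs)
                raise RowError(f"report {report_id!r}: empty drug name")
            role = str(row["role_code"]).strip().upper()
            if role not in ROLE_CODES:
                raise RowError(
                    f"report {report_id!r}: unparseable role_code {row['role_code']!r}"
                )
            roles_by_drug.setdefault(name, set()).add(role)
        pts: set[str] = set()
        outcomes: set[str] = set()
        for _, row in grp.iterrows():
            pts.update(_split_multi(row["pt_code"]))
            for out in _split_multi(row["outcome"]):
                outcomes.add(_canon_categorical(out, _OUTCOME_ALIASES))
        first = grp.iloc[0]
        reports.append(
            Report(
                report_id=str(report_id),
                drugs=tuple(
                    DrugEntry(name, frozenset(roles))
                    for name, roles in sorted(roles_by_drug.items())
                ),
                pts=frozenset(pts),
                reporter_type=_canon_categorical(first["reporter_type"], _REPORTER_ALIASES),
                sex=_canon_categorical(first["sex"], _SEX_ALIASES),
                age_years=_parse_age(first["age"]),
                country=(str(first["country"]).strip() or "unknown")
                if str(first["country"]).strip().casefold() not in {"", "nan", "unknown"}
                else "unknown",
                outcomes=frozenset(outcomes),
            )
        )
    return reports


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Read an optional trade-name → generic mapping (CSV: trade_name,generic)."""
    df = _read_delimited(Path(path))
    _require_columns(df, ("trade_name", "generic"), "synonym table")
    return {
        normalize_drug_name(t): normalize_drug_name(g)
        for t, g in zip(df["trade_name"], df["generic"])
        if normalize_drug_name(t) and normalize_drug_name(g)
    }


def read_reports(
    path: str | Path,
    dialect: str = "flat_case_table",
    synonyms: Mapping[str, str] | None = None,
) -> ReportCollection:
    """Read a report collection from delimited text.

    Two dialects are supported:

    ``flat_case_table``
        One file, one row per report-drug, with report-level fields repeated
        (columns ``report_id, drug_name, role_code, pt_code, reporter_type,
        sex, age, country, outcome``; ``pt_code`` and ``outcome`` may be
        semicolon-separated lists).

    ``faers_like_multi_table``
        ``path`` is a directory holding five delimited files sharing the
        ``report_id`` key, mirroring the FAERS quarterly ASCII tables:
        ``demo`` (report_id, sex, age, country, reporter_type),
        ``drug`` (report_id, drug_name, role_code),
        ``reac`` (report_id, pt_code),
        ``outc`` (report_id, outcome) and
        ``rpsr`` (report_id, report_source; optional, carried through only
        as provenance and not otherwise used).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in {"flat", "flat_case_table"}:
        df = _read_delimited(path)
        _require_columns(df, FLAT_COLUMNS, "flat case table")
        return ReportCollection(_build_reports(df, synonyms))
    if dialect in {"faers-like", "faers_like", "faers_like_multi_table"}:
        return _read_faers_like(path, synonyms)
    raise ValueError(f"unknown dialect {dialect!r}")


def _find_table(directory: Path, stem: str) -> Path:
    for candidate in sorted(directory.glob(f"{stem}*")):
        if candidate.suffix.lower() in {".tsv", ".csv", ".txt"}:
            return candidate
    raise SchemaError(f"faers-like dialect: no {stem} table under {directory}")


def _read_faers_like(
    directory: Path, synonyms: Mapping[str, str] | None
) -> ReportCollection:
    if not directory.is_dir():
        raise SchemaError("faers-like dialect expects a directory of tables")
    demo = _read_delimited(_find_table(directory, "demo"))
    drug = _read_delimited(_find_table(directory, "drug"))
    reac = _read_delimited(_find_table(directory, "reac"))
    outc = _read_delimited(_find_table(directory, "outc"))
    _require_columns(demo, ("report_id", "sex", "age", "country", "reporter_type"), "demo")
    _require_columns(drug, ("report_id", "drug_name", "role_code"), "drug")
    _require_columns(reac, ("report_id", "pt_code"), "reac")
    _require_columns(outc, ("report_id", "outcome"), "outc")
    if demo["report_id"].duplicated().any():
        dupes = demo.loc[demo["report_id"].duplicated(), "report_id"].tolist()
        raise RowError(f"duplicate report_id with conflicting demographics: {dupes[:5]}")

    pts = reac.groupby("report_id")["pt_code"].agg(lambda s: ";".join(s))
    outs = outc.groupby("report_id")["outcome"].agg(lambda s: ";".join(s))
    merged = drug.merge(demo, on="report_id", how="outer")
    merged["drug_name"] = merged["drug_name"].fillna("")
    merged["role_code"] = merged["role_code"].fillna("")
    merged["pt_code"] = merged["report_id"].map(pts).fillna("")
    merged["outcome"] = merged["report_id"].map(outs).fillna("")
    for col in ("reporter_type", "sex", "age", "country"):
        merged[col] = merged[col].fillna("")
    return ReportCollection(_build_reports(merged, synonyms))


def write_reports(collection: ReportCollection, path: str | Path) -> None:
    """Write a collection in the flat dialect (tab-separated, UTF-8).

    A drug listed under several roles is emitted as one row per role so the
    file round-trips exactly through :func:`read_reports`.
    """
    rows: list[dict[str, str]] = []
    for report in collection:
        base = {
            "report_id": report.report_id,
            "pt_code": ";".join(sorted(report.pts)),
            "reporter_type": report.reporter_type,
            "sex": report.sex,
            "age": "" if report.age_years is None else f"{report.age_years:g}",
            "country": report.country,
            "outcome": ";".join(sorted(report.outcomes)),
        }
        if not report.drugs:
            rows.append({**base, "drug_name": "", "role_code": ""})
            continue
        for entry in report.drugs:
            for role in sorted(entry.roles):
                rows.append({**base, "drug_name": entry.name, "role_code": role})
    df = pd.DataFrame(rows, columns=list(FLAT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def mark_cases(collection: ReportCollection, target_pt: str) -> np.ndarray:
    """Boolean flag per report: does it record the target preferred term?"""
    if not str(target_pt).strip():
        raise ValueError("target_pt must be non-empty")
    pt = str(target_pt).strip()
    return np.array([pt in r.pts for r in collection.reports], dtype=bool)


def filter_by_reporter(
    collection: ReportCollection, excluded: Iterable[str]
) -> ReportCollection:
    """Drop reports whose reporter type is in ``excluded`` (sensitivity analysis)."""
    excluded = frozenset(excluded)
    bad = excluded - set(REPORTER_TYPES)
    if bad:
        raise ValueError(f"unknown reporter types: {sorted(bad)}")
    return ReportCollection(
        [r for r in collection if r.reporter_type not in excluded]
    )


def restrict_to_role(
    collection: ReportCollection, roles: Iterable[str]
) -> ReportCollection:
    """Keep only drug entries listed under the given roles; drop drug-less reports.

    Used for the interacting-drugs (role I) subset analysis.
    """
    keep = frozenset(roles)
    if not keep:
        raise ValueError("roles must be non-empty")
    bad = keep - set(ROLE_CODES)
    if bad:
        raise ValueError(f"unknown role codes: {sorted(bad)}")
    out: list[Report] = []
    for report in collection:
        drugs = tuple(
            DrugEntry(e.name, frozenset(e.roles & keep))
            for e in report.drugs
            if e.roles & keep
        )
        if drugs:
            out.append(replace(report, drugs=drugs))
    return ReportCollection(out)


def drop_drugless(collection: ReportCollection) -> ReportCollection:
    """Drop reports with no drug entries (they carry no exposure information)."""
    return ReportCollection([r for r in collection if r.drugs])
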