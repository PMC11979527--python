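"""Cross-referencing detected signals against DDI compendia.

Detected pairs are checked against user-supplied reference tables emulating
two interaction compendia (severity classes per source) and drug-level
torsades-risk annotations.  The funnel classifies consensus-detected pairs
by indexing status, and — going the other way — evaluable pairs indexed by
both sources but flagged by no model are surfaced as negative-DDI
candidates (candidates for alert-fatigue reduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .contingency import canonical_pair
from .models import MODEL_NAMES
from .reports import normalize_drug_name

REFERENCE_SOURCES = ("lexicomp", "drugscom")

SEVERITY_CLASSES: dict[str, frozenset[str]] = {
    "lexicomp": frozenset({"X", "D", "C", "B"}),
    "drugscom": frozenset({"Major", "Moderate", "Minor"}),
}

CREDIBLE_MEDS_TIERS = ("known", "possible", "conditional", "none")
UPTODATE_TIERS = ("highest", "moderate", "low", "none")


@dataclass(frozen=True, slots=True)
class ReferenceEntry:
    pair: tuple[str, str]
    source: str
    severity: str


@dataclass(frozen=True, slots=True)
class DrugAnnotation:
    drug_name: str
    credible_meds_tier: str = "none"
    uptodate_tier: str = "none"


def load_reference(path: str | Path) -> set[ReferenceEntry]:
    """Read a compendium table (CSV/TSV: drug1, drug2, source, severity).

    Pair keys are canonicalized so reversed drug orders collapse; duplicate
    (pair, source) rows collapse with a warning (a conflict keeps the first
    severity seen).
    """
    df = _read(path)
    for col in ("drug1", "drug2", "source", "severity"):
        if col not in df.columns:
            raise ValueError(f"reference table: missing required column {col!r}")
    seen: dict[tuple[tuple[str, str], str], str] = {}
    for idx, row in df.iterrows():
        source = str(row["source"]).strip().casefold()
        if source not in REFERENCE_SOURCES:
            raise ValueError(
                f"reference row {idx}: unknown source {row['source']!r}; "
                f"allowed: {list(REFERENCE_SOURCES)}"
            )
        severity = str(row["severity"]).strip()
        allowed = SEVERITY_CLASSES[source]
        if severity not in allowed:
            raise ValueError(
                f"reference row {idx}: severity {severity!r} not in "
                f"{sorted(allowed)} for source {source!r}"
            )
        pair = canonical_pair(str(row["drug1"]), str(row["drug2"]))
        key = (pair, source)
        if key in seen:
            warnings.warn(
                f"duplicate reference entry for {pair} from {source}; keeping first",
                stacklevel=2,
            )
            continue
        seen[key] = severity
    return {
        ReferenceEntry(pair, source, severity)
        for (pair, source), severity in seen.items()
    }


def load_annotations(path: str | Path) -> set[DrugAnnotation]:
    """Read drug-level risk annotations (CSV/TSV: drug, credible_meds, uptodate)."""
    df = _read(path)
    for col in ("drug", "credible_meds", "uptodate"):
        if col not in df.columns:
            raise ValueError(f"annotation table: missing required column {col!r}")
    out = set()
    for idx, row in df.iterrows():
        cm = str(row["credible_meds"]).strip().casefold() or "none"
        ut = str(row["uptodate"]).strip().casefold() or "none"
        if cm not in CREDIBLE_MEDS_TIERS:
            raise ValueError(f"annotation row {idx}: unknown credible_meds tier {cm!r}")
        if ut not in UPTODATE_TIERS:
            raise ValueError(f"annotation row {idx}: unknown uptodate tier {ut!r}")
        out.add(DrugAnnotation(normalize_drug_name(row["drug"]), cm, ut))
    return out


def _read(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])


@dataclass(slots=True)
class FunnelReport:
    """Counts of the verification funnel plus per-pair category labels."""

    detected_total: int
    indexed_lexicomp: int
    indexed_drugscom: int
    indexed_either: int
    indexed_both: int
    indexed_neither: int
    negative_ddis: list[tuple[str, str]]
    labels: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("detected_total", self.detected_total),
            ("indexed_lexicomp", self.indexed_lexicomp),
            ("indexed_drugscom", self.indexed_drugscom),
            ("indexed_either", self.indexed_either),
            ("indexed_both", self.indexed_both),
            ("indexed_neither", self.indexed_neither),
            ("negative_ddis", len(self.negative_ddis)),
        ]
        return pd.DataFrame(rows, columns=["category", "count"])


def _index_by_pair(reference: Iterable[ReferenceEntry]) -> dict[tuple[str, str], set[str]]:
    sources: dict[tuple[str, str], set[str]] = {}
    for entry in reference:
        sources.setdefault(entry.pair, set()).add(entry.source)
    return sources


def classify_pairs(
    signals: pd.DataFrame,
    reference: Iterable[ReferenceEntry],
    detection: str = "consensus",
) -> FunnelReport:
    """Label detected pairs by compendium indexing; find negative DDIs.

    ``detection`` is ``consensus`` (flagged by all four models, the default)
    or ``any`` (flagged by at least one).  A negative-DDI candidate is a
    pair indexed by both sources, evaluable under all four models with
    n111 at or above the case threshold (it passed pair enumeration), and
    flagged by none.
    """
    if detection not in {"consensus", "any"}:
        raise ValueError("detection must be 'consensus' or 'any'")
    sources = _index_by_pair(reference)
    detected_mask = (
        signals["consensus"].to_numpy(dtype=bool)
        if detection == "consensus"
        else signals["n_models_flagging"].to_numpy() > 0
    )
    rows = []
    negative: list[tuple[str, str]] = []
    all_evaluable = signals[[f"{m}_evaluable" for m in MODEL_NAMES]].all(axis=1)
    none_flagged = signals["n_models_flagging"].to_numpy() == 0
    for i, row in enumerate(signals.itertuples(index=False)):
        pair = (row.drug1, row.drug2)
        src = sources.get(pair, set())
        if detected_mask[i]:
            if {"lexicomp", "drugscom"} <= src:
                label = "indexed_both"
            elif "lexicomp" in src:
                label = "indexed_lexicomp_only"
            elif "drugscom" in src:
                label = "indexed_drugscom_only"
            else:
                label = "indexed_neither"
            rows.append(
                {"drug1": pair[0], "drug2": pair[1], "n111": row.n111, "category": label}
            )
        if (
            {"lexicomp", "drugscom"} <= src
            and bool(all_evaluable.iloc[i])
            and none_flagged[i]
        ):
            negative.append(pair)
    labels = pd.DataFrame(rows, columns=["drug1", "drug2", "n111", "category"])
    n_both = int((labels["category"] == "indexed_both").sum())
    n_lex_only = int((labels["category"] == "indexed_lexicomp_only").sum())
    n_dc_only = int((labels["category"] == "indexed_drugscom_only").sum())
    n_neither = int((labels["category"] == "indexed_neither").sum())
    report = FunnelReport(
        detected_total=int(detected_mask.sum()),
        indexed_lexicomp=n_both + n_lex_only,
        indexed_drugscom=n_both + n_dc_only,
        indexed_either=n_both + n_lex_only + n_dc_only,
        indexed_both=n_both,
        indexed_neither=n_neither,
        negative_ddis=sorted(negative),
        labels=labels,
    )
    # Funnel conservation: categories partition the detected set exactly.
    assert report.indexed_either + report.indexed_neither == report.detected_total
    assert report.indexed_both <= report.indexed_either <= report.detected_total
    return report


def annotate_drugs(
    signals: pd.DataFrame,
    annotations: Iterable[DrugAnnotation] = (),
) -> pd.DataFrame:
    """Per-drug interaction degree over consensus pairs.

    For each drug: number of consensus partners, total co-exposed case
    reports over its consensus pairs, and its risk-tier annotations; sorted
    by partner count descending then name.
    """
    tiers: Mapping[str, DrugAnnotation] = {a.drug_name: a for a in annotations}
    degree: dict[str, int] = {}
    cases: dict[str, int] = {}
    consensus = signals[signals["consensus"].astype(bool)]
    for row in consensus.itertuples(index=False):
        for drug in (row.drug1, row.drug2):
            degree[drug] = degree.get(drug, 0) + 1
            cases[drug] = cases.get(drug, 0) + int(row.n111)
    rows = [
        {
            "drug": drug,
            "n_partners": degree[drug],
            "total_n111": cases[drug],
            "credible_meds": tiers[drug].credible_meds_tier if drug in tiers else "none",
            "uptodate": tiers[drug].uptodate_tier if drug in tiers else "none",
        }
        for drug in degree
    ]
    df = pd.DataFrame(
        rows, columns=["drug", "n_partners", "total_n111", "credible_meds", "uptodate"]
    )
    return df.sort_values(
        ["n_partners", "drug"], ascending=[False, True], ignore_index=True
    )


def edge_list(signals: pd.DataFrame, detection: str = "consensus") -> pd.DataFrame:
    """Network edge list (drug1, drug2, n111) of detected pairs."""
    mask = (
        signals["consensus"].astype(bool)
        if detection == "consensus"
        else signals["n_models_flagging"] > 0
    )
    return signals.loc[mask, ["drug1", "drug2", "n111"]].reset_index(drop=True)
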