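"""End-to-end orchestration: ingest → cases → signals → agreement → funnel.

Runs the whole screen on a report collection (read from file or simulated),
including the sensitivity rerun that excludes nonprofessional reporters,
and writes all outputs as plain delimited text plus a YAML run manifest
(input hashes, thresholds, formula variants, seed) so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_matrix
from .contingency import eligible_pairs, pairs_to_frame
from .demographics import summarize_demographics
from .models import run_all_models, single_drug_ror_table
from .reports import (
    NONPROFESSIONAL_REPORTERS,
    ReportCollection,
    drop_drugless,
    mark_cases,
    read_reports,
)
from .simulate import SyntheticConfig, generate_reports
from .verification import (
    annotate_drugs,
    classify_pairs,
    edge_list,
    load_annotations,
    load_reference,
)


@dataclass(slots=True)
class PipelineConfig:
    """Everything a run needs; exactly one of reports_path / simulate must be set."""

    reports_path: str | None = None
    dialect: str = "flat_case_table"
    simulate: SyntheticConfig | None = None
    seed: int | None = None
    target_pt: str = "10044066"
    min_cases: int = 3
    min_drug_cases: int = 3
    omega_baseline: str = "reciprocal"
    excluded_reporters: tuple[str, ...] = ()
    sensitivity_excluded: tuple[str, ...] = tuple(sorted(NONPROFESSIONAL_REPORTERS))
    reference_path: str | None = None
    annotations_path: str | None = None
    detection: str = "consensus"


@dataclass(slots=True)
class PipelineResult:
    demographics: pd.DataFrame
    single_drug_ror: pd.DataFrame
    pair_counts: pd.DataFrame
    signals: pd.DataFrame
    agreement: pd.DataFrame
    funnel: pd.DataFrame | None
    funnel_labels: pd.DataFrame | None
    negative_ddis: pd.DataFrame | None
    drug_degrees: pd.DataFrame | None
    edges: pd.DataFrame
    sensitivity_signals: pd.DataFrame
    manifest: dict[str, Any] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _analyze(
    collection: ReportCollection, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signal detection on an (already filtered) collection.

    Drug-less reports stay in the denominator: they are unexposed controls,
    and conditioning every stratum on "lists at least one drug" distorts the
    neither-drug stratum of each pair (reports there would be required to
    carry some other drug, inflating its event rate and biasing the
    interaction contrasts).  In FAERS-style data every report lists a drug,
    so this choice only matters for simulated input.
    """
    flags = mark_cases(collection, config.target_pt)
    pairs = eligible_pairs(
        collection, flags,
        min_cases=config.min_cases,
        min_drug_cases=config.min_drug_cases,
    )
    counts = pairs_to_frame(pairs)
    signals = run_all_models(
        pairs, min_cases=config.min_cases, omega_baseline=config.omega_baseline
    )
    return counts, signals


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full screen; optionally write every output file.

    Stages: ingest (or simulate) → reporter filter → case marking →
    demographics → single-drug ROR → pair enumeration → four interaction
    models with consensus → inter-model agreement → compendium funnel →
    sensitivity rerun excluding nonprofessional reporters.
    """
    if (config.reports_path is None) == (config.simulate is None):
        raise ValueError("set exactly one of reports_path or simulate")

    input_hash: str | None = None
    if config.reports_path is not None:
        collection = read_reports(config.reports_path, config.dialect)
        input_hash = _sha256(Path(config.reports_path)) if Path(config.reports_path).is_file() else None
    else:
        collection = generate_reports(config.simulate, seed=config.seed)

    if config.excluded_reporters:
        from .reports import filter_by_reporter

        collection = filter_by_reporter(collection, config.excluded_reporters)

    n_ingested = collection.n_total
    n_with_drugs = drop_drugless(collection).n_total
    case_flags_full = mark_cases(collection, config.target_pt)
    demographics = summarize_demographics(collection, case_flags_full)

    ror = single_drug_ror_table(collection, case_flags_full, min_cases=config.min_cases)
    pair_frame, signals = _analyze(collection, config)
    agreement = agreement_matrix(signals) if not signals.empty else pd.DataFrame()

    funnel = funnel_labels = negative = degrees = None
    reference = None
    if config.reference_path:
        reference = load_reference(config.reference_path)
        report = classify_pairs(signals, reference, detection=config.detection)
        funnel = report.to_frame()
        funnel_labels = report.labels
        negative = pd.DataFrame(report.negative_ddis, columns=["drug1", "drug2"])
    annotations = (
        load_annotations(config.annotations_path) if config.annotations_path else set()
    )
    degrees = annotate_drugs(signals, annotations)
    edges = edge_list(signals, detection=config.detection)

    # Sensitivity rerun: same thresholds and variants, nonprofessionals excluded.
    from .reports import filter_by_reporter

    sens_collection = filter_by_reporter(collection, config.sensitivity_excluded)
    _, sens_signals = _analyze(sens_collection, config)

    manifest: dict[str, Any] = {
        "tdpddi_version": __version__,
        "n_reports_ingested": int(n_ingested),
        "n_reports_with_drugs": int(n_with_drugs),
        "n_cases": int(case_flags_full.sum()),
        "target_pt": config.target_pt,
        "thresholds": {
            "min_cases": config.min_cases,
            "min_drug_cases": config.min_drug_cases,
        },
        "formula_variants": {"omega_baseline": config.omega_baseline},
        "detection": config.detection,
        "excluded_reporters": list(config.excluded_reporters),
        "sensitivity_excluded_reporters": list(config.sensitivity_excluded),
        "seed": config.seed if config.seed is not None else (
            config.simulate.seed if config.simulate else None
        ),
        "input": {
            "reports_path": config.reports_path,
            "reports_sha256": input_hash,
            "simulated": config.simulate is not None,
            "simulate_config_sha256": (
                hashlib.sha256(
                    json.dumps(config.simulate.to_dict(), sort_keys=True).encode()
                ).hexdigest()
                if config.simulate
                else None
            ),
            "reference_path": config.reference_path,
            "annotations_path": config.annotations_path,
        },
    }

    result = PipelineResult(
        demographics=demographics,
        single_drug_ror=ror,
        pair_counts=pair_frame,
        signals=signals,
        agreement=agreement,
        funnel=funnel,
        funnel_labels=funnel_labels,
        negative_ddis=negative,
        drug_degrees=degrees,
        edges=edges,
        sensitivity_signals=sens_signals,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    staging = out_dir.with_name(out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        def dump(df: pd.DataFrame | None, name: str) -> None:
            if df is not None:
                df.to_csv(staging / name, sep="\t", index=False)

        dump(result.demographics, "demographics.tsv")
        dump(result.single_drug_ror, "single_drug_ror.tsv")
        dump(result.pair_counts, "pairs_counts.tsv")
        dump(result.signals, "signals.tsv")
        dump(result.agreement, "agreement.tsv")
        dump(result.funnel, "funnel.tsv")
        dump(result.negative_ddis, "negative_ddis.tsv")
        dump(result.drug_degrees, "drug_degrees.tsv")
        dump(result.edges, "edges.tsv")
        dump(result.sensitivity_signals, "sensitivity_signals.tsv")
        with open(staging / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(result.manifest, fh, sort_keys=True)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
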