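"""Synthetic spontaneous-report generator with known ground truth.

Emulates the features of a large spontaneous reporting system that matter
for drug-pair signal detection: a rare target event, dozens to hundreds of
drugs with skewed exposure frequencies, correlated co-prescription for
designated pairs, per-drug risk elevation, and explicit pairwise synergy.
Single-drug effects are multiplicative on the event probability and an
interaction multiplier adds synergy beyond them, so "both drugs risky, no
interaction" (the negative-DDI phenomenon) is cleanly separated from true
synergy.  Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .contingency import canonical_pair
from .reports import DrugEntry, Report, ReportCollection
from .verification import DrugAnnotation, ReferenceEntry

DEFAULT_TARGET_PT = "10044066"

# Opaque non-target preferred-term codes assigned to non-case reports.
DEFAULT_NOISE_PTS: tuple[str, ...] = tuple(f"1000{i:04d}" for i in range(1, 13))

_AGE_BAND_RANGES: dict[str, tuple[float, float]] = {
    "0-19": (0.0, 20.0),
    "20-39": (20.0, 40.0),
    "40-59": (40.0, 60.0),
    "60-79": (60.0, 80.0),
    ">=80": (80.0, 98.0),
}


@dataclass(frozen=True, slots=True)
class DrugSpec:
    """One simulated drug: marginal exposure probability and risk effect."""

    name: str
    exposure_prob: float
    risk_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.exposure_prob < 1:
            raise ValueError("exposure_prob must be in (0, 1)")
        if self.risk_multiplier <= 0:
            raise ValueError("risk_multiplier must be positive")


@dataclass(frozen=True, slots=True)
class PairSpec:
    """A designated drug pair: co-prescription boost and synergy."""

    drug_a: str
    drug_b: str
    corx_boost: float = 0.0
    interaction_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.corx_boost <= 1:
            raise ValueError("corx_boost must be in [0, 1]")
        if self.interaction_multiplier <= 0:
            raise ValueError("interaction_multiplier must be positive")

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.drug_a, self.drug_b)


@dataclass(slots=True)
class SyntheticConfig:
    n_reports: int
    baseline_event_prob: float
    drugs: list[DrugSpec]
    pairs: list[PairSpec] = field(default_factory=list)
    target_pt: str = DEFAULT_TARGET_PT
    noise_pts: tuple[str, ...] = DEFAULT_NOISE_PTS
    reporter_distribution: dict[str, float] = field(default_factory=dict)
    sex_distribution: dict[str, float] = field(default_factory=dict)
    age_distribution: dict[str, float] = field(default_factory=dict)
    country_distribution: dict[str, float] = field(default_factory=dict)
    outcome_distribution: dict[str, float] = field(default_factory=dict)
    p_interacting_role: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError("config needs at least one drug")
        if not 0 < self.baseline_event_prob < 1:
            raise ValueError("baseline_event_prob must be in (0, 1)")
        names = [d.name for d in self.drugs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate drug names in config")
        for dist_name in (
            "reporter_distribution",
            "sex_distribution",
            "age_distribution",
            "country_distribution",
            "outcome_distribution",
        ):
            dist = getattr(self, dist_name)
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{dist_name} must sum to 1")

    # -- file representation (plain key-value tree) ---------------------

    def to_dict(self) -> dict:
        data = asdict(self)
        data["noise_pts"] = list(self.noise_pts)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        drugs = [DrugSpec(**d) for d in data["drugs"]]
        pairs = [PairSpec(**p) for p in data.get("pairs", [])]
        kwargs = {k: v for k, v in data.items() if k not in {"drugs", "pairs", "noise_pts"}}
        return cls(
            drugs=drugs,
            pairs=pairs,
            noise_pts=tuple(data.get("noise_pts", DEFAULT_NOISE_PTS)),
            **kwargs,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _draw_categorical(
    rng: np.random.Generator, dist: dict[str, float], n: int, default: str
) -> np.ndarray:
    if not dist:
        return np.full(n, default, dtype=object)
    cats = list(dist.keys())
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.array(cats, dtype=object)[idx]


def generate_reports(
    config: SyntheticConfig,
    seed: int | None = None,
    return_diagnostics: bool = False,
):
    """Simulate a report collection from a config.

    Exposures are sampled independently per drug, then each designated
    pair's co-prescription boost adds the partner (with probability
    ``corx_boost``) to reports carrying exactly one member.  The event
    probability is baseline x product of exposed risk multipliers x product
    of co-exposed interaction multipliers, clamped at 0.99.  Case reports
    record the target preferred term; others a random noise term.  Role
    codes: one random exposed drug on a case report is the primary suspect
    (PS), drugs of co-exposed designated pairs are marked interacting (I)
    with probability ``p_interacting_role``, all others concomitant (C).

    With ``return_diagnostics`` the per-report event probabilities are also
    returned (for calibration checks).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    k = len(config.drugs)
    names = [d.name for d in config.drugs]
    name_to_idx = {name: i for i, name in enumerate(names)}
    probs = np.array([d.exposure_prob for d in config.drugs])
    log_rm = np.log(np.array([d.risk_multiplier for d in config.drugs]))

    exposed = rng.random((n, k)) < probs

    # Co-prescription boosts, evaluated on the independent draws.
    base = exposed.copy()
    for pair in config.pairs:
        if pair.corx_boost <= 0:
            continue
        ia, ib = name_to_idx[pair.drug_a], name_to_idx[pair.drug_b]
        add_b = base[:, ia] & ~base[:, ib] & (rng.random(n) < pair.corx_boost)
        add_a = base[:, ib] & ~base[:, ia] & (rng.random(n) < pair.corx_boost)
        exposed[:, ib] |= add_b
        exposed[:, ia] |= add_a

    log_p = np.log(config.baseline_event_prob) + exposed @ log_rm
    pair_co = {}
    for pair in config.pairs:
        ia, ib = name_to_idx[pair.drug_a], name_to_idx[pair.drug_b]
        co = exposed[:, ia] & exposed[:, ib]
        pair_co[(ia, ib)] = co
        if pair.interaction_multiplier != 1.0:
            log_p = log_p + co * np.log(pair.interaction_multiplier)
    p_event = np.minimum(np.exp(log_p), 0.99)
    event = rng.random(n) < p_event

    # Role codes: start concomitant, mark interacting pairs, then primary suspect.
    role = np.full((n, k), 0, dtype=np.int8)  # 0=C, 1=I, 2=PS
    for pair in config.pairs:
        ia, ib = name_to_idx[pair.drug_a], name_to_idx[pair.drug_b]
        mark = pair_co[(ia, ib)] & (rng.random(n) < config.p_interacting_role)
        role[mark, ia] = 1
        role[mark, ib] = 1
    u_ps = rng.random(n)

    reporter = _draw_categorical(rng, config.reporter_distribution, n, "unknown")
    sex = _draw_categorical(rng, config.sex_distribution, n, "unknown")
    band = _draw_categorical(rng, config.age_distribution, n, "unknown")
    u_age = rng.random(n)
    country = _draw_categorical(rng, config.country_distribution, n, "unknown")
    outcome = _draw_categorical(rng, config.outcome_distribution, n, "unknown")
    noise_idx = rng.integers(0, len(config.noise_pts), size=n)

    role_names = ("C", "I", "PS")
    rows, cols = np.nonzero(exposed)
    width = max(7, len(str(n)))
    reports: list[Report] = []
    ptr = 0
    m = rows.shape[0]
    for i in range(n):
        start = ptr
        while ptr < m and rows[ptr] == i:
            ptr += 1
        drug_idx = cols[start:ptr]
        entries: list[DrugEntry] = []
        if drug_idx.size:
            ps_slot = int(u_ps[i] * drug_idx.size) if event[i] else -1
            for slot, j in enumerate(drug_idx):
                code = "PS" if slot == ps_slot else role_names[role[i, j]]
                entries.append(DrugEntry(names[j], frozenset({code})))
        if band[i] in _AGE_BAND_RANGES:
            low, high = _AGE_BAND_RANGES[band[i]]
            age: float | None = round(low + u_age[i] * (high - low), 1)
        else:
            age = None
        reports.append(
            Report(
                report_id=f"R{i:0{width}d}",
                drugs=tuple(entries),
                pts=frozenset(
                    {config.target_pt if event[i] else config.noise_pts[noise_idx[i]]}
                ),
                reporter_type=str(reporter[i]),
                sex=str(sex[i]),
                age_years=age,
                country=str(country[i]),
                outcomes=frozenset({str(outcome[i])}),
            )
        )
    collection = ReportCollection(reports)
    if return_diagnostics:
        return collection, {"p_event": p_event, "exposed": exposed}
    return collection


def ground_truth(config: SyntheticConfig) -> list[tuple[str, str]]:
    """The designated synergy pairs (interaction multiplier > 1), canonicalized."""
    return sorted(
        p.pair for p in config.pairs if p.interaction_multiplier > 1.0
    )


def no_synergy_pairs(config: SyntheticConfig) -> list[tuple[str, str]]:
    """Designated pairs whose drugs are risky but carry no synergy."""
    specs = {d.name: d for d in config.drugs}
    return sorted(
        p.pair
        for p in config.pairs
        if p.interaction_multiplier == 1.0
        and specs[p.drug_a].risk_multiplier > 1.0
        and specs[p.drug_b].risk_multiplier > 1.0
    )


# --------------------------------------------------------------------------
# The fixed benchmark: the study conditions every end-to-end test runs under.

_BENCHMARK_STRUCTURE_SEED = 202309  # fixes exposure probabilities, not the stream

#: Reporter mix: ~93% professional / 7% nonprofessional (consumer + lawyer).
BENCHMARK_REPORTERS = {
    "other_health_professional": 0.380,
    "physician": 0.367,
    "pharmacist": 0.108,
    "unknown": 0.077,
    "consumer": 0.051,
    "lawyer": 0.017,
}

BENCHMARK_SEX = {"male": 0.324, "female": 0.557, "unknown": 0.119}

BENCHMARK_AGE = {
    "0-19": 0.042,
    "20-39": 0.145,
    "40-59": 0.234,
    "60-79": 0.277,
    ">=80": 0.106,
    "unknown": 0.196,
}

BENCHMARK_COUNTRY = {
    "united states": 0.414,
    "japan": 0.047,
    "china": 0.019,
    "other": 0.445,
    "unknown": 0.075,
}

BENCHMARK_OUTCOME = {
    "death": 0.084,
    "life_threatening": 0.395,
    "disability": 0.001,
    "hospitalization": 0.304,
    "required_intervention": 0.004,
    "other": 0.205,
    "unknown": 0.007,
}


def benchmark_default() -> SyntheticConfig:
    """The fixed published benchmark configuration.

    60 drugs with exposure probabilities log-uniform in [0.002, 0.05]
    (drawn once from a fixed structure seed); a rare event at baseline
    probability 5e-3; five synergy pairs (interaction multiplier 8,
    co-prescription boost 0.3) among inert drugs; five no-synergy pairs of
    risky drugs (risk multiplier 3 each, no interaction, boost 0.3); one
    negative-control pair linking the two most-exposed inert drugs
    (no risk, no interaction, boost 0.3) so a commonly co-prescribed inert
    combination is observable at the case threshold; 40+ inert drugs;
    200,000 reports; seed 1.
    """
    rng = np.random.default_rng(_BENCHMARK_STRUCTURE_SEED)
    probs = np.exp(rng.uniform(np.log(0.002), np.log(0.05), 60))
    names = [f"d{i + 1:02d}" for i in range(60)]
    drugs = [
        DrugSpec(
            name=names[i],
            exposure_prob=float(probs[i]),
            risk_multiplier=3.0 if 10 <= i < 20 else 1.0,
        )
        for i in range(60)
    ]
    pairs = [
        PairSpec(names[2 * j], names[2 * j + 1], corx_boost=0.3, interaction_multiplier=8.0)
        for j in range(5)
    ]
    pairs += [
        PairSpec(names[10 + 2 * j], names[11 + 2 * j], corx_boost=0.3, interaction_multiplier=1.0)
        for j in range(5)
    ]
    inert_idx = sorted(range(20, 60), key=lambda i: -probs[i])[:2]
    pairs.append(
        PairSpec(names[inert_idx[0]], names[inert_idx[1]], corx_boost=0.3, interaction_multiplier=1.0)
    )
    return SyntheticConfig(
        n_reports=200_000,
        baseline_event_prob=5e-3,
        drugs=drugs,
        pairs=pairs,
        reporter_distribution=dict(BENCHMARK_REPORTERS),
        sex_distribution=dict(BENCHMARK_SEX),
        age_distribution=dict(BENCHMARK_AGE),
        country_distribution=dict(BENCHMARK_COUNTRY),
        outcome_distribution=dict(BENCHMARK_OUTCOME),
        p_interacting_role=0.5,
        seed=1,
    )


def benchmark_negative_control(config: SyntheticConfig) -> tuple[str, str]:
    """The planted inert co-prescribed pair (the negative-DDI exemplar)."""
    specs = {d.name: d for d in config.drugs}
    for p in config.pairs:
        if (
            p.interaction_multiplier == 1.0
            and specs[p.drug_a].risk_multiplier == 1.0
            and specs[p.drug_b].risk_multiplier == 1.0
        ):
            return p.pair
    raise ValueError("config has no inert co-prescribed pair")


def benchmark_reference(config: SyntheticConfig) -> set[ReferenceEntry]:
    """Synthetic compendium table aligned with the benchmark's ground truth.

    The no-synergy risk pairs and the negative-control pair are indexed by
    both sources (the latter with the highest severity class, mirroring the
    real-world pattern of severely flagged combinations that never show a
    reporting signal); three synergy pairs are indexed by both, one by each
    single source.
    """
    synergy = ground_truth(config)
    risk = no_synergy_pairs(config)
    entries: set[ReferenceEntry] = set()
    for pair in risk:
        entries.add(ReferenceEntry(pair, "lexicomp", "D"))
        entries.add(ReferenceEntry(pair, "drugscom", "Major"))
    negative = benchmark_negative_control(config)
    entries.add(ReferenceEntry(negative, "lexicomp", "X"))
    entries.add(ReferenceEntry(negative, "drugscom", "Major"))
    for pair in synergy[:3]:
        entries.add(ReferenceEntry(pair, "lexicomp", "X"))
        entries.add(ReferenceEntry(pair, "drugscom", "Major"))
    if len(synergy) > 3:
        entries.add(ReferenceEntry(synergy[3], "lexicomp", "C"))
    if len(synergy) > 4:
        entries.add(ReferenceEntry(synergy[4], "drugscom", "Moderate"))
    return entries


def benchmark_annotations(config: SyntheticConfig) -> set[DrugAnnotation]:
    """Drug-level risk tiers for the benchmark's designated drugs."""
    out: set[DrugAnnotation] = set()
    for pair in no_synergy_pairs(config):
        for drug in pair:
            out.add(DrugAnnotation(drug, "known", "highest"))
    for pair in ground_truth(config):
        for drug in pair:
            out.add(DrugAnnotation(drug, "possible", "moderate"))
    return out


def reference_to_frame(entries: Iterable[ReferenceEntry]):
    import pandas as pd

    rows = [
        {"drug1": e.pair[0], "drug2": e.pair[1], "source": e.source, "severity": e.severity}
        for e in sorted(entries, key=lambda e: (e.pair, e.source))
    ]
    return pd.DataFrame(rows, columns=["drug1", "drug2", "source", "severity"])


def annotations_to_frame(entries: Iterable[DrugAnnotation]):
    import pandas as pd

    rows = [
        {"drug": e.drug_name, "credible_meds": e.credible_meds_tier, "uptodate": e.uptodate_tier}
        for e in sorted(entries, key=lambda e: e.drug_name)
    ]
    return pd.DataFrame(rows, columns=["drug", "credible_meds", "uptodate"])
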