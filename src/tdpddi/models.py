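"""Disproportionality statistics for single drugs and drug pairs.

Single drugs are screened with the reporting odds ratio (ROR).  Drug pairs
are screened with four frequency-statistical interaction models, each with
its own positivity criterion, evaluated on the 4x2 pair table:

* Omega shrinkage measure — log2 observed-to-expected ratio for the
  co-exposed stratum with +0.5 shrinkage, against a no-interaction baseline
  built from the three other strata; positive when the lower credibility
  bound Omega_025 exceeds 0.
* Chi-square statistic — Yates-corrected one-sample chi-square of the
  co-exposed event split against the same baseline expectation, reported as
  a signed square root (positive for excess risk); positive when chi > 2.
* Combination risk ratio (CRR) — the pair's proportional reporting ratio
  relative to the neither-drug stratum, divided by the larger single-drug
  PRR; positive when PRR_combo > 2, the Yates chi-square of the combination
  vs reference 2x2 exceeds 4, and CRR > 2.
* Additive model — the observed interaction contrast on the risk-difference
  scale, p11 - p10 - p01 + p00; positive when the contrast exceeds 0.

Every criterion additionally requires at least ``min_cases`` (default 3)
co-exposed case reports, n111 >= 3.  Results are three-valued: flagged,
not flagged, or not evaluable (degenerate table); not-evaluable never
counts as a signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contingency import PairCounts, SingleDrugCounts

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True, slots=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    evaluable: bool
    flag: bool


def reporting_odds_ratio(counts: SingleDrugCounts, min_cases: int = 3) -> RorResult:
    """ROR = (a*d)/(b*c) with a log-scale Wald 95% CI.

    If any cell is zero the Haldane–Anscombe correction (+0.5 on all four
    cells) is applied.  The signal criterion is ROR > 2, lower CI bound > 1
    and at least ``min_cases`` exposed case reports.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if a + b + c + d == 0:
        return RorResult(math.nan, math.nan, math.nan, 0, False, False)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    ror = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(ror) - Z95 * se)
    ci_high = math.exp(math.log(ror) + Z95 * se)
    flag = ror > 2 and ci_low > 1 and a >= min_cases
    return RorResult(ror, ci_low, ci_high, a, True, flag)


@dataclass(frozen=True, slots=True)
class BaselineResult:
    g00: float
    g10: float
    g01: float
    g11_expected: float
    e111: float
    fallback_used: bool
    evaluable: bool


def no_interaction_baseline(
    counts: PairCounts,
    variant: str = "reciprocal",
    shrinkage: bool = True,
) -> BaselineResult:
    """Expected co-exposed event rate under no interaction.

    Stratum event proportions are shrunk, g_ij = (n_ij1 + 0.5)/(n_ij+ + 0.5),
    which keeps them strictly positive.  The ``reciprocal`` variant solves
    1/g11 = 1/g10 + 1/g01 - 1/g00; when that reciprocal sum is not positive
    (both drugs carrying large relative risks) it falls back to
    g11 = max(g10, g01).  The ``max`` variant uses the fallback throughout.
    g11 is capped at 1 and e111 = g11 * n11+.
    """
    if variant not in {"reciprocal", "max"}:
        raise ValueError(f"unknown baseline variant {variant!r}")
    if min(counts.n00p, counts.n10p, counts.n01p, counts.n11p) == 0:
        return BaselineResult(
            math.nan, math.nan, math.nan, math.nan, math.nan, False, False
        )
    if shrinkage:
        g00 = (counts.n001 + 0.5) / (counts.n00p + 0.5)
        g10 = (counts.n101 + 0.5) / (counts.n10p + 0.5)
        g01 = (counts.n011 + 0.5) / (counts.n01p + 0.5)
    else:
        g00 = counts.n001 / counts.n00p
        g10 = counts.n101 / counts.n10p
        g01 = counts.n011 / counts.n01p
        if min(g00, g10, g01) <= 0:
            return BaselineResult(g00, g10, g01, math.nan, math.nan, False, False)
    fallback = False
    if variant == "reciprocal":
        recip = 1 / g10 + 1 / g01 - 1 / g00
        if recip > 0:
            g11 = 1 / recip
        else:
            g11 = max(g10, g01)
            fallback = True
    else:
        g11 = max(g10, g01)
    g11 = min(g11, 1.0)
    return BaselineResult(g00, g10, g01, g11, g11 * counts.n11p, fallback, True)


@dataclass(frozen=True, slots=True)
class OmegaResult:
    g00: float
    g10: float
    g01: float
    g11_expected: float
    e111: float
    omega: float
    omega025: float
    fallback_used: bool
    evaluable: bool
    flag: bool


def omega_shrinkage(
    counts: PairCounts,
    baseline: BaselineResult | None = None,
    min_cases: int = 3,
    baseline_variant: str = "reciprocal",
) -> OmegaResult:
    """Omega = log2((n111 + 0.5)/(E111 + 0.5)) with lower credibility bound.

    Omega_025 = Omega - 3.3 * n111^(-1/2) - 2 * n111^(-3/4); the signal
    criterion is Omega_025 > 0 with n111 >= min_cases.
    """
    if baseline is None:
        baseline = no_interaction_baseline(counts, variant=baseline_variant)
    if not baseline.evaluable:
        return OmegaResult(
            baseline.g00, baseline.g10, baseline.g01, math.nan, math.nan,
            math.nan, math.nan, False, False, False,
        )
    n111 = counts.n111
    omega = math.log2((n111 + 0.5) / (baseline.e111 + 0.5))
    if n111 > 0:
        omega025 = omega - 3.3 * n111 ** -0.5 - 2.0 * n111 ** -0.75
    else:
        omega025 = -math.inf
    flag = omega025 > 0 and n111 >= min_cases
    return OmegaResult(
        baseline.g00, baseline.g10, baseline.g01,
        baseline.g11_expected, baseline.e111,
        omega, omega025, baseline.fallback_used, True, flag,
    )


@dataclass(frozen=True, slots=True)
class ChiResult:
    e111: float
    chi: float
    evaluable: bool
    flag: bool


def chi_square_yates(
    counts: PairCounts,
    baseline: BaselineResult | None = None,
    min_cases: int = 3,
    baseline_variant: str = "reciprocal",
) -> ChiResult:
    """Signed Yates-corrected chi statistic of the co-exposed event split.

    The observed split (n111, n110) is compared against the no-interaction
    expectation (e111, n11+ - e111).  With the continuity term
    max(|n111 - e111| - 0.5, 0), chi^2 = term^2 * (1/e111 + 1/e110) and chi
    carries the sign of n111 - e111, so the criterion chi > 2 is one-sided
    for excess risk.
    """
    if baseline is None:
        baseline = no_interaction_baseline(counts, variant=baseline_variant)
    if not baseline.evaluable:
        return ChiResult(math.nan, math.nan, False, False)
    e111 = baseline.e111
    e110 = counts.n11p - e111
    if e111 <= 0 or e110 <= 0:
        return ChiResult(e111, math.nan, False, False)
    term = max(abs(counts.n111 - e111) - 0.5, 0.0)
    chi2 = term * term * (1 / e111 + 1 / e110)
    chi = math.copysign(math.sqrt(chi2), counts.n111 - e111) if term > 0 else 0.0
    flag = chi > 2 and counts.n111 >= min_cases
    return ChiResult(e111, chi, True, flag)


@dataclass(frozen=True, slots=True)
class CrrResult:
    prr_combo: float
    prr10: float
    prr01: float
    crr: float
    chi2_combo: float
    evaluable: bool
    flag: bool


def _yates_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Yates-corrected Pearson chi-square of [[a, b], [c, d]]."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return math.nan
    term = max(abs(a * d - b * c) - n / 2, 0.0)
    return n * term * term / (r1 * r2 * c1 * c2)


def combination_risk_ratio(counts: PairCounts, min_cases: int = 3) -> CrrResult:
    """Combination risk ratio against the neither-drug reference stratum.

    PRR_combo = (n111/n11+)/(n001/n00+), PRR10 and PRR01 analogously for the
    single-drug strata, CRR = PRR_combo / max(PRR10, PRR01).  When the
    reference stratum has no cases (n001 = 0) a +0.5 continuity correction
    is applied to the four cells defining each ratio.  chi2_combo is the
    Yates chi-square of the 2x2 [[n111, n110], [n001, n000]].
    """
    if min(counts.n11p, counts.n10p, counts.n01p, counts.n00p) == 0:
        return CrrResult(math.nan, math.nan, math.nan, math.nan, math.nan, False, False)

    if counts.n001 > 0:
        def prr(x: int, nx: int) -> float:
            return (x / nx) / (counts.n001 / counts.n00p)
    else:
        def prr(x: int, nx: int) -> float:
            return ((x + 0.5) / (nx + 0.5)) / (0.5 / (counts.n00p + 0.5))

    prr_combo = prr(counts.n111, counts.n11p)
    prr10 = prr(counts.n101, counts.n10p)
    prr01 = prr(counts.n011, counts.n01p)
    denom = max(prr10, prr01)
    chi2_combo = _yates_chi2_2x2(counts.n111, counts.n110, counts.n001, counts.n000)
    if denom <= 0 or not math.isfinite(denom) or math.isnan(chi2_combo):
        return CrrResult(prr_combo, prr10, prr01, math.nan, chi2_combo, False, False)
    crr = prr_combo / denom
    flag = (
        prr_combo > 2
        and chi2_combo > 4
        and crr > 2
        and counts.n111 >= min_cases
    )
    return CrrResult(prr_combo, prr10, prr01, crr, chi2_combo, True, flag)


@dataclass(frozen=True, slots=True)
class AdditiveResult:
    p11: float
    p10: float
    p01: float
    p00: float
    contrast: float
    evaluable: bool
    flag: bool


def additive_contrast(counts: PairCounts, min_cases: int = 3) -> AdditiveResult:
    """Interaction contrast on the risk-difference scale.

    Uses unshrunk observed stratum proportions p_ij = n_ij1/n_ij+; the
    criterion is the point estimate p11 - p10 - p01 + p00 > 0 with no
    variance term, which makes the model deliberately sensitive (purely
    multiplicative joint risks are super-additive and get flagged).
    """
    if min(counts.n11p, counts.n10p, counts.n01p, counts.n00p) == 0:
        return AdditiveResult(math.nan, math.nan, math.nan, math.nan, math.nan, False, False)
    p11 = counts.n111 / counts.n11p
    p10 = counts.n101 / counts.n10p
    p01 = counts.n011 / counts.n01p
    p00 = counts.n001 / counts.n00p
    contrast = p11 - p10 - p01 + p00
    flag = contrast > 0 and counts.n111 >= min_cases
    return AdditiveResult(p11, p10, p01, p00, contrast, True, flag)


MODEL_NAMES = ("omega", "chi", "crr", "additive")

SIGNALS_COLUMNS = [
    "drug1", "drug2", "n111", "n11+", "n10+", "n01+", "n00+",
    "e111", "omega", "omega025", "omega_fallback", "omega_evaluable", "omega_flag",
    "chi", "chi_evaluable", "chi_flag",
    "prr_combo", "prr10", "prr01", "crr", "chi2_combo", "crr_evaluable", "crr_flag",
    "contrast", "additive_evaluable", "additive_flag",
    "n_models_flagging", "consensus",
]


def run_all_models(
    pairs: list[tuple[tuple[str, str], PairCounts]],
    min_cases: int = 3,
    omega_baseline: str = "reciprocal",
) -> pd.DataFrame:
    """Evaluate all four interaction models on every pair.

    Returns one row per pair, sorted by pair key, with each model's
    statistics, evaluability and flag, plus the all-four consensus flag
    (a pair not evaluable under a model can never reach consensus).
    """
    rows = []
    for (low, high), pc in sorted(pairs, key=lambda item: item[0]):
        baseline = no_interaction_baseline(pc, variant=omega_baseline)
        om = omega_shrinkage(pc, baseline, min_cases=min_cases)
        ch = chi_square_yates(pc, baseline, min_cases=min_cases)
        cr = combination_risk_ratio(pc, min_cases=min_cases)
        ad = additive_contrast(pc, min_cases=min_cases)
        flags = (om.flag, ch.flag, cr.flag, ad.flag)
        rows.append(
            {
                "drug1": low,
                "drug2": high,
                "n111": pc.n111,
                "n11+": pc.n11p,
                "n10+": pc.n10p,
                "n01+": pc.n01p,
                "n00+": pc.n00p,
                "e111": om.e111,
                "omega": om.omega,
                "omega025": om.omega025,
                "omega_fallback": om.fallback_used,
                "omega_evaluable": om.evaluable,
                "omega_flag": om.flag,
                "chi": ch.chi,
                "chi_evaluable": ch.evaluable,
                "chi_flag": ch.flag,
                "prr_combo": cr.prr_combo,
                "prr10": cr.prr10,
                "prr01": cr.prr01,
                "crr": cr.crr,
                "chi2_combo": cr.chi2_combo,
                "crr_evaluable": cr.evaluable,
                "crr_flag": cr.flag,
                "contrast": ad.contrast,
                "additive_evaluable": ad.evaluable,
                "additive_flag": ad.flag,
                "n_models_flagging": int(sum(flags)),
                "consensus": all(flags),
            }
        )
    return pd.DataFrame(rows, columns=SIGNALS_COLUMNS)


def single_drug_ror_table(
    collection,
    case_flags: np.ndarray,
    drugs: list[str] | None = None,
    min_cases: int = 3,
) -> pd.DataFrame:
    """ROR screen for every drug (or a given list) against the event."""
    from .contingency import single_drug_counts
    from .reports import normalize_drug_name

    if drugs is None:
        seen: set[str] = set()
        for report in collection:
            seen.update(report.drug_names)
        drugs = sorted(seen)
    else:
        drugs = sorted({normalize_drug_name(d) for d in drugs})
    rows = []
    for drug in drugs:
        counts = single_drug_counts(collection, case_flags, drug)
        res = reporting_odds_ratio(counts, min_cases=min_cases)
        rows.append(
            {
                "drug": drug,
                "a": counts.a,
                "b": counts.b,
                "c": counts.c,
                "d": counts.d,
                "ror": res.ror,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "evaluable": res.evaluable,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["drug", "a", "b", "c", "d", "ror", "ci_low", "ci_high", "evaluable", "flag"],
    )
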