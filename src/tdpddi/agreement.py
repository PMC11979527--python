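"""Inter-model concordance: Cohen's kappa and proportionate agreement.

Two models' signal flags over the same pair universe form a 2x2 concordance
table (a both-positive, b first-only, c second-only, d both-negative).
Kappa corrects the observed agreement for chance; P_positive and P_negative
are the proportionate agreements on positive and negative ratings.  Pairs
not evaluable under either model are excluded pairwise (kappa is defined
over dichotomous ratings only) and the exclusion count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .models import MODEL_NAMES

Z95 = 1.959963984540054


@dataclass(frozen=True, slots=True)
class AgreementTable:
    a: int  # both positive
    b: int  # first positive only
    c: int  # second positive only
    d: int  # both negative

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class AgreementResult:
    po: float
    pe: float
    kappa: float
    kappa_ci_low: float
    kappa_ci_high: float
    p_positive: float
    p_negative: float
    evaluable: bool


def agreement_table(
    flags_first: np.ndarray, flags_second: np.ndarray
) -> AgreementTable:
    """Tally the four concordance categories of two aligned flag vectors."""
    first = np.asarray(flags_first, dtype=bool)
    second = np.asarray(flags_second, dtype=bool)
    if first.shape != second.shape:
        raise ValueError("flag vectors must be aligned (same length)")
    return AgreementTable(
        a=int(np.sum(first & second)),
        b=int(np.sum(first & ~second)),
        c=int(np.sum(~first & second)),
        d=int(np.sum(~first & ~second)),
    )


def agreement_stats(table: AgreementTable) -> AgreementResult:
    """Closed-form kappa with large-sample CI, P_positive and P_negative.

    po = (a+d)/n, pe = ((a+b)(a+c) + (c+d)(b+d))/n^2,
    kappa = (po - pe)/(1 - pe),
    CI = kappa +/- 1.96 * sqrt(po(1-po) / (n (1-pe)^2)),
    P_positive = 2a/(2a+b+c), P_negative = 2d/(2d+b+c).

    Constant raters (pe = 1) leave kappa undefined: not evaluable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty agreement table")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    p_positive = 2 * a / (2 * a + b + c) if (2 * a + b + c) > 0 else math.nan
    p_negative = 2 * d / (2 * d + b + c) if (2 * d + b + c) > 0 else math.nan
    if pe >= 1.0:
        return AgreementResult(po, pe, math.nan, math.nan, math.nan,
                               p_positive, p_negative, False)
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return AgreementResult(
        po, pe, kappa, kappa - Z95 * se, kappa + Z95 * se,
        p_positive, p_negative, True,
    )


def interpret_kappa(kappa: float) -> str:
    """Verbal agreement band for a kappa value."""
    if math.isnan(kappa):
        return "not_evaluable"
    if kappa < 0:
        return "less_than_chance"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "excellent"


# The six model pairs in reporting order (omega first, additive last).
MODEL_PAIR_ORDER: tuple[tuple[str, str], ...] = tuple(
    combinations(MODEL_NAMES, 2)
)


def agreement_matrix(signals: pd.DataFrame) -> pd.DataFrame:
    """Pairwise concordance of the four models' flags over evaluated pairs.

    For each of the six model pairs, pairs evaluable under both models are
    kept (complete-case pairwise) and the concordance statistics computed;
    ``n_excluded`` counts the dropped pairs.
    """
    if signals.empty:
        raise ValueError("signals table is empty")
    rows = []
    for first, second in MODEL_PAIR_ORDER:
        both = (
            signals[f"{first}_evaluable"].to_numpy(dtype=bool)
            & signals[f"{second}_evaluable"].to_numpy(dtype=bool)
        )
        table = agreement_table(
            signals.loc[both, f"{first}_flag"].to_numpy(dtype=bool),
            signals.loc[both, f"{second}_flag"].to_numpy(dtype=bool),
        )
        res = agreement_stats(table) if table.n else None
        rows.append(
            {
                "model1": first,
                "model2": second,
                "n_pairs": table.n,
                "n_excluded": int((~both).sum()),
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "p_positive": res.p_positive if res else math.nan,
                "p_negative": res.p_negative if res else math.nan,
                "kappa": res.kappa if res else math.nan,
                "kappa_ci_low": res.kappa_ci_low if res else math.nan,
                "kappa_ci_high": res.kappa_ci_high if res else math.nan,
                "interpretation": interpret_kappa(res.kappa) if res else "not_evaluable",
            }
        )
    return pd.DataFrame(rows)
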