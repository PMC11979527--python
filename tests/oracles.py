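"""Independent straight-line recomputations used as test oracles.

Everything here is deliberately naive — plain loops over reports and
transliterations of the closed-form statistics — and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_single_counts(reports, case_flags, drug):
    a = b = c = d = 0
    for report, is_case in zip(reports, case_flags):
        names = {e.name for e in report.drugs}
        if drug in names and is_case:
            a += 1
        elif drug in names:
            b += 1
        elif is_case:
            c += 1
        else:
            d += 1
    return a, b, c, d


def brute_pair_counts(reports, case_flags, drug1, drug2):
    """Eight cells in n111..n000 order for the sorted pair (drug1 < drug2)."""
    cells = {}
    for report, is_case in zip(reports, case_flags):
        names = {e.name for e in report.drugs}
        key = (int(drug1 in names), int(drug2 in names), int(bool(is_case)))
        cells[key] = cells.get(key, 0) + 1
    order = [(1, 1, 1), (1, 1, 0), (1, 0, 1), (1, 0, 0),
             (0, 1, 1), (0, 1, 0), (0, 0, 1), (0, 0, 0)]
    return tuple(cells.get(k, 0) for k in order)


def brute_eligible_pairs(reports, case_flags, min_cases=3, min_drug_cases=3):
    """Exhaustive enumeration over every pair of drugs seen anywhere."""
    drug_case = {}
    all_drugs = set()
    for report, is_case in zip(reports, case_flags):
        names = {e.name for e in report.drugs}
        all_drugs |= names
        if is_case:
            for name in names:
                drug_case[name] = drug_case.get(name, 0) + 1
    screened = sorted(d for d in all_drugs if drug_case.get(d, 0) >= min_drug_cases)
    out = {}
    for d1, d2 in combinations(screened, 2):
        cells = brute_pair_counts(reports, case_flags, d1, d2)
        if cells[0] >= min_cases:
            out[(d1, d2)] = cells
    return out


def ror_oracle(a, b, c, d):
    """(ror, ci_low, ci_high) with +0.5 on all cells when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def baseline_oracle(cells, shrink=True):
    """(g00, g10, g01, g11, e111, fallback) from the eight cells."""
    n111, n110, n101, n100, n011, n010, n001, n000 = cells
    n11p, n10p, n01p, n00p = n111 + n110, n101 + n100, n011 + n010, n001 + n000
    if shrink:
        g00 = (n001 + 0.5) / (n00p + 0.5)
        g10 = (n101 + 0.5) / (n10p + 0.5)
        g01 = (n011 + 0.5) / (n01p + 0.5)
    else:
        g00, g10, g01 = n001 / n00p, n101 / n10p, n011 / n01p
    s = 1 / g10 + 1 / g01 - 1 / g00
    if s > 0:
        g11, fallback = 1 / s, False
    else:
        g11, fallback = max(g10, g01), True
    g11 = min(g11, 1.0)
    return g00, g10, g01, g11, g11 * n11p, fallback


def omega_oracle(n111, e111):
    omega = math.log2((n111 + 0.5) / (e111 + 0.5))
    omega025 = omega - 3.3 * n111 ** -0.5 - 2 * n111 ** -0.75
    return omega, omega025


def chi_oracle(n111, n11p, e111):
    e110 = n11p - e111
    term = max(abs(n111 - e111) - 0.5, 0.0)
    chi2 = term * term * (1 / e111 + 1 / e110)
    return math.copysign(math.sqrt(chi2), n111 - e111) if term else 0.0


def yates_2x2_oracle(a, b, c, d):
    n = a + b + c + d
    term = max(abs(a * d - b * c) - n / 2, 0.0)
    return n * term * term / ((a + b) * (c + d) * (a + c) * (b + d))


def crr_oracle(cells):
    """(prr_combo, prr10, prr01, crr, chi2_combo)."""
    n111, n110, n101, n100, n011, n010, n001, n000 = cells
    n11p, n10p, n01p, n00p = n111 + n110, n101 + n100, n011 + n010, n001 + n000
    if n001 > 0:
        ref = n001 / n00p
        prr_combo = (n111 / n11p) / ref
        prr10 = (n101 / n10p) / ref
        prr01 = (n011 / n01p) / ref
    else:
        ref = 0.5 / (n00p + 0.5)
        prr_combo = ((n111 + 0.5) / (n11p + 0.5)) / ref
        prr10 = ((n101 + 0.5) / (n10p + 0.5)) / ref
        prr01 = ((n011 + 0.5) / (n01p + 0.5)) / ref
    crr = prr_combo / max(prr10, prr01) if max(prr10, prr01) > 0 else math.nan
    return prr_combo, prr10, prr01, crr, yates_2x2_oracle(n111, n110, n001, n000)


def additive_oracle(cells):
    n111, n110, n101, n100, n011, n010, n001, n000 = cells
    n11p, n10p, n01p, n00p = n111 + n110, n101 + n100, n011 + n010, n001 + n000
    p11, p10, p01, p00 = n111 / n11p, n101 / n10p, n011 / n01p, n001 / n00p
    return p11 - p10 - p01 + p00


def agreement_oracle(a, b, c, d):
    """(po, pe, kappa, p_positive, p_negative)."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
    kappa = (po - pe) / (1 - pe)
    return po, pe, kappa, 2 * a / (2 * a + b + c), 2 * d / (2 * d + b + c)
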