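"""The five statistics: worked examples, library cross-checks, properties."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tdpddi as t
from tdpddi.contingency import PairCounts, SingleDrugCounts
from tdpddi.models import BaselineResult, _yates_chi2_2x2

from oracles import baseline_oracle, crr_oracle, ror_oracle

TOL = 1e-9


# ---------------------------------------------------------------- ROR


def test_ror_identity_table_is_null():
    res = t.reporting_odds_ratio(SingleDrugCounts(1, 1, 1, 1))
    assert res.ror == pytest.approx(1.0, abs=TOL)
    assert not res.flag


def test_ror_worked_example_matches_closed_form():
    res = t.reporting_odds_ratio(SingleDrugCounts(20, 80, 100, 9800))
    ror, lo, hi = ror_oracle(20, 80, 100, 9800)
    assert res.ror == pytest.approx(24.5, abs=TOL)
    assert res.ci_low == pytest.approx(lo, abs=TOL)
    assert res.ci_high == pytest.approx(hi, abs=TOL)
    assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (14.45, 41.55)
    assert res.flag


def test_ror_zero_cell_continuity_correction():
    res = t.reporting_odds_ratio(SingleDrugCounts(0, 10, 5, 985))
    assert res.ror == pytest.approx((0.5 * 985.5) / (10.5 * 5.5), abs=TOL)
    assert not res.flag  # fewer than 3 exposed cases
    assert res.n_cases == 0


def test_ror_all_zero_table_is_not_evaluable():
    res = t.reporting_odds_ratio(SingleDrugCounts(0, 0, 0, 0))
    assert not res.evaluable and not res.flag


def test_ror_matches_statsmodels_table2x2():
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    rng = np.random.default_rng(5)
    for _ in range(25):
        a, b, c, d = rng.integers(1, 400, size=4)
        res = t.reporting_odds_ratio(SingleDrugCounts(int(a), int(b), int(c), int(d)))
        table = sm.Table2x2([[a, b], [c, d]])
        assert res.ror == pytest.approx(table.oddsratio, rel=1e-12)
        lo, hi = table.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)


# ---------------------------------------------------- no-interaction baseline


def test_baseline_equal_risks_reduces_to_background():
    # g10 = g01 = g00 implies the expected co-exposed rate equals background.
    pc = PairCounts(n111=0, n110=100, n101=5, n100=995, n011=5, n010=995,
                    n001=25, n000=4975)
    base = t.no_interaction_baseline(pc, shrinkage=False)
    assert base.g10 == base.g01 == base.g00
    assert base.g11_expected == pytest.approx(base.g00, abs=TOL)
    assert base.e111 == pytest.approx(base.g00 * pc.n11p, abs=TOL)
    assert not base.fallback_used


def test_baseline_worked_example_unshrunk():
    pc = PairCounts(n111=40, n110=460, n101=20, n100=1980, n011=16, n010=1984,
                    n001=50, n000=9950)
    base = t.no_interaction_baseline(pc, shrinkage=False)
    assert (base.g00, base.g10, base.g01) == (0.005, 0.010, 0.008)
    # 1/g11 = 100 + 125 - 200 = 25
    assert base.g11_expected == pytest.approx(0.04, abs=TOL)
    assert base.e111 == pytest.approx(20.0, abs=TOL)
    assert not base.fallback_used


def test_baseline_fallback_when_reciprocal_sum_negative():
    # g10=0.03, g01=0.02, g00=0.01: 33.3 + 50 - 100 < 0 -> fallback to max.
    pc = PairCounts(n111=10, n110=90, n101=30, n100=970, n011=20, n010=980,
                    n001=10, n000=990)
    base = t.no_interaction_baseline(pc, shrinkage=False)
    assert base.fallback_used
    assert base.g11_expected == pytest.approx(0.03, abs=TOL)


def test_baseline_not_evaluable_with_empty_stratum():
    pc = PairCounts(n111=3, n110=0, n101=0, n100=0, n011=2, n010=8, n001=5, n000=85)
    base = t.no_interaction_baseline(pc)
    assert not base.evaluable
    assert not t.omega_shrinkage(pc).flag
    assert not t.chi_square_yates(pc).evaluable


def test_max_variant_ignores_reciprocal_form():
    pc = PairCounts(n111=40, n110=460, n101=20, n100=1980, n011=16, n010=1984,
                    n001=50, n000=9950)
    base = t.no_interaction_baseline(pc, variant="max", shrinkage=False)
    assert base.g11_expected == pytest.approx(0.010, abs=TOL)


# ------------------------------------------------------------------ omega


def _counts_with(n111, n110):
    # co-exposed stratum as given; outer strata only matter via the baseline,
    # which worked examples inject directly.
    return PairCounts(n111=n111, n110=n110, n101=5, n100=995, n011=5, n010=995,
                      n001=25, n000=4975)


def _baseline(e111):
    return BaselineResult(0.005, 0.005, 0.005, 0.01, e111, False, True)


def test_omega_zero_when_observed_equals_expected():
    res = t.omega_shrinkage(_counts_with(20, 480), _baseline(20.0))
    assert res.omega == pytest.approx(0.0, abs=TOL)
    assert res.omega025 < 0
    assert not res.flag


def test_omega_worked_example_forty_vs_twenty():
    res = t.omega_shrinkage(_counts_with(40, 460), _baseline(20.0))
    expected = math.log2(40.5 / 20.5)
    penalty = 3.3 * 40 ** -0.5 + 2 * 40 ** -0.75
    assert res.omega == pytest.approx(expected, abs=TOL)
    assert res.omega025 == pytest.approx(expected - penalty, abs=TOL)
    assert round(res.omega, 3) == 0.982
    assert round(res.omega025, 3) == pytest.approx(0.335, abs=1e-3)
    assert res.flag


def test_omega_three_cases_zero_expected():
    res = t.omega_shrinkage(_counts_with(3, 497), _baseline(0.0))
    expected = math.log2(3.5 / 0.5)
    penalty = 3.3 * 3 ** -0.5 + 2 * 3 ** -0.75
    assert res.omega == pytest.approx(expected, abs=TOL)
    assert res.omega025 == pytest.approx(expected - penalty, abs=TOL)
    assert res.omega025 > 0 and res.flag


@given(n111=st.integers(1, 5000), e111=st.floats(0.0, 5000.0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_omega_shrinkage_is_conservative_and_bounded(n111, e111):
    res = t.omega_shrinkage(_counts_with(n111, 0), _baseline(e111))
    assert res.omega025 < res.omega
    if n111 > e111 > 0:
        assert res.omega < math.log2(n111 / e111)  # +0.5 pulls toward 0


@given(e111=st.floats(0.5, 400.0), lo=st.integers(1, 800), delta=st.integers(1, 200))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_omega_monotone_in_observed_count(e111, lo, delta):
    first = t.omega_shrinkage(_counts_with(lo, 0), _baseline(e111))
    second = t.omega_shrinkage(_counts_with(lo + delta, 0), _baseline(e111))
    assert second.omega >= first.omega
    assert second.omega025 >= first.omega025


# -------------------------------------------------------------------- chi


def test_chi_zero_at_expected_value():
    res = t.chi_square_yates(_counts_with(20, 480), _baseline(20.0))
    assert res.chi == 0.0
    assert not res.flag


def test_chi_worked_example():
    res = t.chi_square_yates(_counts_with(40, 460), _baseline(20.0))
    chi2 = 19.5 ** 2 * (1 / 20 + 1 / 480)
    assert res.chi == pytest.approx(math.sqrt(chi2), abs=TOL)
    assert round(res.chi, 2) == 4.45
    assert res.flag


def test_chi_zero_within_continuity_band():
    res = t.chi_square_yates(_counts_with(20, 480), _baseline(19.6))
    assert res.chi == 0.0


def test_chi_deficit_is_negative_and_never_flags():
    res = t.chi_square_yates(_counts_with(5, 495), _baseline(60.0))
    assert res.chi < -2
    assert not res.flag


def test_chi_degenerate_expectation_not_evaluable():
    res = t.chi_square_yates(_counts_with(5, 495), _baseline(0.0))
    assert not res.evaluable and not res.flag
    res = t.chi_square_yates(_counts_with(5, 495), _baseline(500.0))
    assert not res.evaluable


# -------------------------------------------------------------------- CRR


def test_crr_null_when_all_stratum_risks_equal():
    pc = PairCounts(n111=5, n110=995, n101=5, n100=995, n011=5, n010=995,
                    n001=5, n000=995)
    res = t.combination_risk_ratio(pc)
    assert res.prr_combo == pytest.approx(1.0, abs=TOL)
    assert res.crr == pytest.approx(1.0, abs=TOL)
    assert not res.flag


def test_crr_worked_example():
    pc = PairCounts(n111=40, n110=460, n101=20, n100=1980, n011=16, n010=1984,
                    n001=50, n000=9950)
    res = t.combination_risk_ratio(pc)
    assert res.prr_combo == pytest.approx(16.0, abs=TOL)
    assert res.prr10 == pytest.approx(2.0, abs=TOL)
    assert res.prr01 == pytest.approx(1.6, abs=TOL)
    assert res.crr == pytest.approx(8.0, abs=TOL)
    assert res.chi2_combo == pytest.approx(crr_oracle(
        (40, 460, 20, 1980, 16, 1984, 50, 9950))[4], abs=TOL)
    assert round(res.chi2_combo, 1) == 306.4
    assert res.flag


def test_crr_strong_single_drug_masks_combination():
    # combination PRR 13 but one drug alone has PRR 12: CRR ~ 1.08, no flag.
    pc = PairCounts(n111=26, n110=374, n101=60, n100=940, n011=5, n010=995,
                    n001=50, n000=9950)
    res = t.combination_risk_ratio(pc)
    assert res.prr10 == pytest.approx(12.0, abs=TOL)
    assert res.prr_combo == pytest.approx(13.0, abs=TOL)
    assert res.crr == pytest.approx(13 / 12, abs=TOL)
    assert not res.flag


def test_crr_zero_reference_cases_uses_continuity_correction():
    pc = PairCounts(n111=4, n110=96, n101=2, n100=198, n011=1, n010=199,
                    n001=0, n000=1000)
    res = t.combination_risk_ratio(pc)
    expected = ((4.5 / 100.5)) / (0.5 / 1000.5)
    assert res.prr_combo == pytest.approx(expected, abs=TOL)
    assert res.evaluable


def test_combination_chi2_matches_scipy_yates():
    from scipy.stats import chi2_contingency

    rng = np.random.default_rng(3)
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
        ours = _yates_chi2_2x2(a, b, c, d)
        theirs = chi2_contingency(np.array([[a, b], [c, d]]), correction=True)[0]
        assert ours == pytest.approx(theirs, rel=1e-12, abs=1e-12)


# --------------------------------------------------------------- additive


def test_additive_exact_additivity_is_boundary():
    pc = PairCounts(n111=5, n110=995, n101=5, n100=995, n011=5, n010=995,
                    n001=5, n000=995)
    res = t.additive_contrast(pc)
    assert res.contrast == pytest.approx(0.0, abs=TOL)
    assert not res.flag


def test_additive_worked_example():
    # p11=0.08, p10=0.01, p01=0.008, p00=0.005 -> contrast 0.067
    pc = PairCounts(n111=40, n110=460, n101=20, n100=1980, n011=16, n010=1984,
                    n001=50, n000=9950)
    res = t.additive_contrast(pc)
    assert res.contrast == pytest.approx(0.067, abs=TOL)
    assert res.flag


def test_additive_flags_pure_multiplicativity():
    # multiplicative risks 0.01/0.02/0.03/0.06 are super-additive: contrast 0.02
    pc = PairCounts(n111=60, n110=940, n101=20, n100=980, n011=30, n010=970,
                    n001=10, n000=990)
    res = t.additive_contrast(pc)
    assert res.contrast == pytest.approx(0.02, abs=TOL)
    assert res.flag


def test_additive_not_evaluable_with_empty_stratum():
    pc = PairCounts(n111=3, n110=0, n101=0, n100=0, n011=1, n010=9, n001=2, n000=98)
    res = t.additive_contrast(pc)
    assert not res.evaluable and not res.flag


# ----------------------------------------------------------- joint behavior


@st.composite
def pair_tables(draw):
    cells = [draw(st.integers(0, 400)) for _ in range(8)]
    return PairCounts(*cells)


@given(pc=pair_tables())
@settings(max_examples=300, deadline=None, derandomize=True)
def test_all_statistics_symmetric_under_drug_swap(pc):
    swapped = pc.swapped()
    base_a = t.no_interaction_baseline(pc)
    base_b = t.no_interaction_baseline(swapped)
    assert base_a.evaluable == base_b.evaluable
    if base_a.evaluable:
        assert base_a.e111 == pytest.approx(base_b.e111, rel=1e-12, abs=1e-12)
    for fn in (t.omega_shrinkage, t.chi_square_yates, t.combination_risk_ratio,
               t.additive_contrast):
        ra, rb = fn(pc), fn(swapped)
        assert ra.flag == rb.flag
        assert ra.evaluable == rb.evaluable


@given(pc=pair_tables())
@settings(max_examples=300, deadline=None, derandomize=True)
def test_flags_imply_evaluability_and_case_minimum(pc):
    for fn in (t.omega_shrinkage, t.chi_square_yates, t.combination_risk_ratio,
               t.additive_contrast):
        res = fn(pc)
        if res.flag:
            assert res.evaluable
            assert pc.n111 >= 3


def test_baseline_matches_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(50):
        cells = tuple(int(x) for x in rng.integers(1, 300, size=8))
        pc = PairCounts(*cells)
        ours = t.no_interaction_baseline(pc)
        g00, g10, g01, g11, e111, fb = baseline_oracle(cells)
        assert ours.g11_expected == pytest.approx(g11, rel=1e-12)
        assert ours.e111 == pytest.approx(e111, rel=1e-12)
        assert ours.fallback_used == fb


def test_run_all_models_consensus_is_intersection():
    rng = np.random.default_rng(23)
    pairs = []
    for i in range(40):
        cells = tuple(int(x) for x in rng.integers(0, 200, size=8))
        pairs.append(((f"a{i:02d}", f"b{i:02d}"), PairCounts(*cells)))
    df = t.run_all_models(pairs)
    manual = (
        df["omega_flag"] & df["chi_flag"] & df["crr_flag"] & df["additive_flag"]
    )
    assert (df["consensus"] == manual).all()
    assert (df["n_models_flagging"] ==
            df[["omega_flag", "chi_flag", "crr_flag", "additive_flag"]].sum(axis=1)).all()
    # deterministic sorted order
    assert list(df["drug1"]) == sorted(df["drug1"])
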