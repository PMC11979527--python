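# tdpddi — drug–drug interaction signal detection for torsades de pointes

`tdpddi` screens case-level spontaneous adverse-event reports (FAERS-style
data) for **drug pairs** whose co-reporting with torsades de pointes (TdP,
MedDRA PT 10044066) exceeds what the two drugs explain separately. It is
aimed at pharmacovigilance analysts and clinical pharmacists who want to
separate clinically meaningful QT/TdP drug–drug interactions (DDIs) from
the flood of compendium alerts — including finding **negative DDIs**:
combinations severely flagged by interaction compendia that show no
reporting signal at all, candidates for alert-fatigue reduction.

## What it computes

From a collection of reports (each with drugs under role codes PS/SS/C/I, a
set of preferred terms, and demographics) the pipeline builds, per drug
pair, the 4×2 table *n<sub>ijk</sub>* (i, j = exposure to each drug,
k = event) and evaluates four frequency-statistical interaction models:

| Model | Statistic | Signal criterion |
|---|---|---|
| Ω shrinkage measure | Ω = log₂((n₁₁₁+0.5)/(E₁₁₁+0.5)) | Ω₀₂₅ > 0, n₁₁₁ ≥ 3 |
| Chi-square (Yates) | signed χ of (n₁₁₁, n₁₁₊−n₁₁₁) vs (E₁₁₁, n₁₁₊−E₁₁₁) | χ > 2, n₁₁₁ ≥ 3 |
| Combination risk ratio | CRR = PRR₁₁ / max(PRR₁₀, PRR₀₁) | PRR₁₁ > 2, χ² > 4, CRR > 2, n₁₁₁ ≥ 3 |
| Additive model | P₁₁ − P₁₀ − P₀₁ + P₀₀ | contrast > 0, n₁₁₁ ≥ 3 |

The no-interaction expectation E₁₁₁ = g₁₁·n₁₁₊ uses shrunk stratum rates
g<sub>ij</sub> = (n<sub>ij1</sub>+0.5)/(n<sub>ij+</sub>+0.5) and the
reciprocal model 1/g₁₁ = 1/g₁₀ + 1/g₀₁ − 1/g₀₀ (fallback max(g₁₀, g₀₁)
when the sum is non-positive; `--omega-baseline max` selects the simpler
variant throughout). Ω₀₂₅ = Ω − 3.3·n₁₁₁^(−1/2) − 2·n₁₁₁^(−3/4).

A **consensus signal** is a pair flagged by all four models. Around the
pair screen the package also provides: the single-drug reporting odds
ratio ROR = (a·d)/(b·c) with log-scale 95% CI (signal: ROR > 2, lower
bound > 1, a ≥ 3); Cohen's κ with proportionate positive/negative
agreement between every two models' flag vectors; a demographic summary of
cases; cross-referencing against user-supplied compendium tables
(Lexicomp-style X/D/C/B, Drugs.com-style Major/Moderate/Minor) with the
detection funnel and negative-DDI listing; and a sensitivity rerun
excluding nonprofessional reporters (consumers, lawyers).

A seeded synthetic-report generator with known ground truth (per-drug risk
multipliers, co-prescription boosts, explicit interaction multipliers)
makes the whole pipeline testable without any data download.

## Worked example

```python
>>> import tdpddi as t
>>> from tdpddi.contingency import SingleDrugCounts, PairCounts
>>> r = t.reporting_odds_ratio(SingleDrugCounts(a=20, b=80, c=100, d=9800))
>>> round(r.ror, 1), round(r.ci_low, 2), round(r.ci_high, 2), r.flag
(24.5, 14.45, 41.55, True)
>>> pc = PairCounts(n111=40, n110=460, n101=20, n100=1980,
...                 n011=16, n010=1984, n001=50, n000=9950)
>>> cr = t.combination_risk_ratio(pc)
>>> cr.prr_combo, cr.prr10, cr.prr01, cr.crr, round(cr.chi2_combo, 1), cr.flag
(16.0, 2.0, 1.6, 8.0, 306.4, True)
```

The drug pair is reported 16× more often with the event than the
neither-drug stratum, and 8× more than its stronger member alone — a clear
combination signal.

End to end on the built-in benchmark (200,000 simulated reports, five
planted synergy pairs, five risky-but-non-interacting pairs, one inert
co-prescribed control):

```bash
$ tdpddi run --benchmark --seed 1 --out-dir results/
cases: 2578  eligible pairs: 508  consensus signals: 160
outputs written to results/
```

All five planted synergy pairs are among the 160 consensus signals, the
additive model flags the most pairs (403, vs 164–227 for the others), and
the inert control pair — indexed by both synthetic compendia — appears in
`negative_ddis.tsv`. Outputs are plain TSV plus a YAML manifest that makes
the run byte-for-byte reproducible.

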