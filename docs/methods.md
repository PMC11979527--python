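# Methods

## Setting and data model

The package analyzes spontaneous adverse-event reports. A report carries a
set of drugs (each under one or more FAERS-style role codes: primary
suspect PS, secondary suspect SS, concomitant C, interacting I), a set of
MedDRA preferred terms (PTs, treated as opaque strings — no dictionary or
hierarchy is consulted), a reporter type, and demographics. A *case* is a
report recording the target PT (default 10044066, torsades de pointes).
All counting uses the deduplicated set of drug names within a report: a
drug listed under several roles counts once. Drug-name normalization is
trim + case-fold only; mapping trade names to generics is out of scope
(an optional user-supplied synonym CSV is honored when given), so pairs of
a brand and its own generic can in principle appear — downstream
compendium verification, which uses generic names, is the guard.

By default exposure counts a drug under any role; `restrict_to_role`
supports the interacting-drugs-only (role I) subset analysis. One report is
one case: no cross-report deduplication is attempted (that is an upstream
cleaning step for real data).

### Drug-less reports stay in the denominator

Reports with no drug entry cannot contribute to any exposed stratum, but
they are genuine unexposed controls. Excluding them conditions the
neither-drug stratum of every pair on carrying *some other* drug, which
inflates that stratum's event rate relative to the single-drug strata and
biases both the additive contrast and the reciprocal baseline toward
spurious positive interaction. On the synthetic benchmark this exclusion
measurably manufactures a signal on a planted inert pair (chi +2.25 and a
positive contrast, versus chi −1.10 and a negative contrast with the full
denominator). The pipeline therefore keeps all reports in N. For real
FAERS-style extracts the choice is vacuous — every report lists at least
one drug.

## Contingency tables and pair enumeration

Per pair the 4×2 table n_ijk (i, j exposure, k event) is assembled by a
two-pass stream: case reports first (candidate pairs and their co-exposed
case counts n111), then all reports for the remaining margins, with sparse
counters keyed by pair — no dense drugs × drugs matrix is ever built.
Candidate drugs must appear in at least `min_drug_cases` case reports
(default 3) and pairs must reach `min_cases` co-exposed case reports
(n111 ≥ 3 by default); both thresholds are configuration. Pairs are
unordered, canonicalized by lexicographic sort of the normalized names;
every pair statistic is invariant under the swap (property-tested).

## The four interaction models

All four evaluate the same table; results are three-valued (flagged / not
flagged / not evaluable) and a pair not evaluable under a model can never
reach consensus.

**No-interaction baseline.** Stratum event rates are shrunk,
g_ij = (n_ij1 + 0.5)/(n_ij+ + 0.5), which keeps them strictly positive.
The expected co-exposed rate solves 1/g11 = 1/g10 + 1/g01 − 1/g00. On the
relative-risk scale r = g/g00 this is 1/r11 = 1/r10 + 1/r01 − 1, which
dominates the multiplicative prediction whenever it is valid
((r10−1)(r01−1) ≥ 0 implies harmonic ≥ multiplicative) but diverges as
1/r10 + 1/r01 → 1 and is undefined beyond; when the reciprocal sum is not
positive the implementation falls back to g11 = max(g10, g01), and g11 is
always capped at 1. The fallback makes the baseline *sub*-multiplicative
exactly for pairs of two strong single-drug risks — such pairs (for
example two drugs that each triple the event rate, combining
multiplicatively to nine-fold) are flagged by Ω whenever reported often
enough. This is a documented property of this baseline family, not an
implementation accident; the `max` variant (selectable via
`omega_baseline="max"`) behaves the same way in that region.

**Ω shrinkage measure.** Ω = log₂((n111 + 0.5)/(E111 + 0.5)) with
E111 = g11·n11+. The +0.5 terms shrink extreme ratios toward zero
(for n111 > E111, Ω < log₂(n111/E111), property-tested). The lower
credibility bound Ω₀₂₅ = Ω − 3.3·n111^(−1/2) − 2·n111^(−3/4) is the
standard closed-form approximation for this measure family; the criterion
Ω₀₂₅ > 0 makes the model markedly conservative at small n111 (at
n111 = 10 the penalty is ≈ 1.4, i.e. the observed count must exceed ~2.7×
expected).

**Chi-square statistic.** A one-sample Yates-corrected chi-square of the
co-exposed event split (n111, n11+ − n111) against the same baseline
expectation, with continuity term max(|n111 − E111| − 0.5, 0); reported as
a signed square root so the criterion χ > 2 is one-sided for excess risk.
Sharing the baseline with Ω is a design choice: the two models are then
expected to agree closely, differing only in how they penalize small
counts. Not evaluable when E111 = 0 or E111 = n11+.

**Combination risk ratio.** Reference stratum is "neither drug":
PRR₁₁ = (n111/n11+)/(n001/n00+), PRR₁₀ and PRR₀₁ analogously, and
CRR = PRR₁₁/max(PRR₁₀, PRR₀₁) asks whether the combination outreports the
stronger of its members by more than two-fold. A +0.5 continuity
correction applies to the defining cells only when the reference stratum
has no cases. χ² is the ordinary Yates chi-square of
[[n111, n110], [n001, n000]] (verified against scipy).

**Additive model.** The interaction contrast on the risk-difference scale,
P₁₁ − P₁₀ − P₀₁ + P₀₀ with unshrunk observed proportions, and no variance
term: the criterion is the raw point estimate. Two deliberate consequences:
purely multiplicative joint risks are super-additive, contrast
(r₁−1)(r₂−1)·g00 > 0, so risky-but-non-interacting pairs are flagged given
power; and for a truly inert pair the contrast is a zero-mean noise
variable, so the flag is near a coin flip. Both effects reproduce the
known over-detection behavior of this model; it is best read through its
intersection with the others.

Boundary criteria (>0, >2, >4) are evaluated as exact strict inequalities;
at count scales below 10⁸ accumulated floating-point error is far from the
thresholds.

## Single-drug screen, agreement, verification

The ROR uses (a·d)/(b·c) with a log-scale Wald 95% CI; the
Haldane–Anscombe +0.5 on all four cells applies only when a cell is zero
(cross-checked against statsmodels on non-degenerate tables). Signal:
ROR > 2, lower bound > 1, a ≥ 3.

Model concordance uses the 2×2 flag-agreement table over the pairs
evaluable under both models (pairwise complete-case; exclusions reported):
κ = (p_o − p_e)/(1 − p_e) with the large-sample CI
κ ± 1.96·√(p_o(1 − p_o)/(n(1 − p_e)²)), plus proportionate agreements
P_positive = 2a/(2a + b + c) and P_negative = 2d/(2d + b + c), and the
conventional verbal bands (slight/fair/moderate/substantial/excellent).
κ is cross-checked against scikit-learn.

Verification consumes user-supplied tables emulating two compendia
(severity vocabularies validated but never ordered or interpreted) and
drug-level risk tiers. The funnel partitions consensus-detected pairs by
indexing status (either/both/neither; a switch relaxes "detected" to
any-model). A **negative DDI** is a pair indexed by *both* sources,
evaluable under all four models with n111 at the case threshold, and
flagged by none — "not detected" is meaningless for pairs never evaluated.

Demographic summaries assign one category per case and dimension; multiple
recorded outcomes collapse to the worst (death > life-threatening >
disability > hospitalization > required intervention > other > unknown).
Percentages are rounded half-up to one decimal.

## The synthetic generator and benchmark

`generate_reports` draws, per report: independent per-drug exposures
(marginal probabilities from the config), then for each designated pair a
co-prescription boost (the missing partner is added with probability
`corx_boost` when exactly one member is present, evaluated on the
independent draws so pair order cannot matter); an event with probability
baseline × Π(risk multipliers of exposed drugs) × Π(interaction
multipliers of co-exposed designated pairs), clamped at 0.99; one PT
(target if case, a random noise code otherwise); role codes (one random
exposed drug on a case report becomes PS; co-exposed designated pairs are
marked I with probability 0.5; the rest C); and categorical demographics.
A single integer seed fixes the entire stream.

The fixed benchmark emulates the study conditions at desk scale: 200,000
reports; baseline event probability 5×10⁻³; 60 drugs with exposure
probabilities log-uniform on [0.002, 0.05] (drawn once from a fixed
structure seed and published as part of the config); five synergy pairs
(interaction multiplier 8, boost 0.3) among otherwise inert drugs; five
no-synergy pairs of risky drugs (risk multiplier 3 each, multiplicative
combination, boost 0.3); one negative-control pair linking the two
most-exposed inert drugs (boost 0.3, no risk, no interaction) — chosen by
that fixed rule so the control is observable well above the n111 ≥ 3
threshold; and a reporter mix of ~93% professionals. Demographic
categoricals follow the case-characteristics profile of a large TdP case
series (55.7% female, 6.8% nonprofessional reporters, 8.4% fatal, etc.),
so the demographic summary can be sanity-checked against its configured
truth. A companion synthetic compendium table indexes the risk pairs and
the control by both sources and three synergy pairs by both, one by each
single source; it is generated, clearly synthetic, and carries no content
from any real compendium.

What the generator deliberately does **not** emulate: duplicate or
follow-up reports, trade-name aliasing, reporting trends over time,
MedDRA co-coding structure, missing-drug masking, or FAERS's true event
rarity (~4×10⁻⁴) and drug count (hundreds) — the benchmark trades those
for a desk-scale run with usable power. Passing benchmark tests therefore
demonstrates correctness of the statistical machinery and the expected
qualitative model ordering under known ground truth, not calibration on
real FAERS extracts.

Benchmark outcomes at seed 1, for orientation: 2,578 cases; 508 eligible
pairs; per-model signals additive 403 ≥ chi 227 ≥ crr 218 ≥ Ω 164
(the additive-most, Ω-fewest ordering); 160 consensus signals including
all five synergy plants; the control pair surfaces as the one negative
DDI. The no-synergy multiplicative pairs are flagged by all four models —
for Ω this follows from the fallback region of its baseline (see above)
and is reported as-is rather than adjusted away. Because the additive flag
on a truly inert pair is a coin flip, the negative-DDI count at other
seeds honestly varies between 0 and 1.

Consensus sets are only partly stable under the sensitivity rerun
(excluding the ~7% nonprofessional reports): the synergy plants always
remain consensus, but borderline confounded pairs — co-exposure with a
genuinely interacting or risky drug induces real secondary signals —
reshuffle at the margin (12 of 160 at seed 1).

## Numerical and engineering choices

* Not-evaluable is distinct from not-flagged everywhere (empty strata,
  degenerate expectations, constant raters); it propagates so that
  consensus, agreement denominators and the negative-DDI rule all treat it
  as "no rating", never as a negative rating.
* All outputs are plain TSV plus a YAML manifest (thresholds, formula
  variants, seed, input hashes); reruns from the same manifest are
  byte-identical (tested). Output directories are staged and swapped so a
  failed run leaves no partial results.
* Synthetic configs serialize to YAML and round-trip exactly.
* Test oracles are independent straight-line recomputations (plain loops
  and transliterated formulas) kept apart from the implementation;
  scipy/statsmodels/scikit-learn serve as external cross-checks where they
  implement the same standard quantity.
* Problem sizes used in the test suite: randomized oracle-equivalence
  fixtures of 200 reports × 30 drugs × 100 repetitions; the 200,000-report
  benchmark is simulated once per session and shared across tests.

## Known limitations

* The Ω/chi baseline family is discontinuous at the fallback boundary
  (1/r10 + 1/r01 = 1): expected rates jump from the cap to max(g10, g01).
  Pairs near the boundary can swing between a strong deficit and a strong
  excess; interpret flags for two-strong-risk pairs with the CRR alongside.
* The additive criterion has no variance term by construction, so its
  single-model flags carry a ~50% false-positive rate on truly inert pairs
  with n111 ≥ 3; it contributes discrimination only through the consensus.
* κ confidence intervals use the large-sample normal approximation and are
  unclipped (the upper bound can exceed 1).
* Signals are reporting disproportionalities, not causal effects; no
  multiple-testing correction is applied, matching standard practice for
  hypothesis-generating pharmacovigilance screens.
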