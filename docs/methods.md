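# Methods

This note documents the models, conventions and design choices behind
`gvarm`, in the order the pipeline applies them.

## Segmentation conventions

A sleep episode belongs to the calendar date of its **offset** — the
morning it ends — so "sleep of day N" is the night leading into day N
and "awake of day N" spans from that morning's offset to the onset of
the night that follows. This makes the two pairings used downstream
temporally ordered: type-1 pairs (awake N−1 → sleep N) and type-2
pairs (sleep N → awake N) both point forward in time, which the rule
miner's AC constraint requires.

Windows are closed at their start and open at their end: a reading
exactly at sleep onset is a sleep reading, a reading exactly at offset
is an awake reading, and no reading is double-counted. Readings before
the first sleep offset or after the last onset fall outside every
window and are excluded. When a wearable reports several sleep bouts
on one day, only the longest (main) episode is used; naps fold into
awake time.

Segments are flagged *complete* when their reading coverage — readings
present over readings expected at the sampling interval — is at least
`min_coverage` (default 0.7). Incomplete segments are profiled as
missing and dropped from pairs with logged counts rather than silently
discarded; the flag guards the GV metrics against sparse segments, and
0.7 is a pragmatic choice in the absence of an established convention
for gap handling in sleep-segmented CGM.

## GV metric conventions

* Standard deviations are sample (n−1) throughout, matching common GV
  software; a single-reading segment has sd 0 by convention.
* The adaptive target range is G_L = mean − k·sd, G_H = mean + k·sd
  with k = 1 by default. `tir` counts readings inside the range with
  *inclusive* bounds; `mge` averages readings *strictly* outside — the
  two are complementary, so every reading is inside or outside exactly
  once. `mge`/`mgn` reuse the same adaptive range as `tir` (a fixed
  clinical 70–180 band can be obtained by computing the metrics
  directly with explicit bounds, but the adaptive range is the package
  default because the whole metric suite is personalised).
* LBGI/HBGI use the risk transform r(g) = 1.509·((ln g)^1.084 − 5.381)
  and average 10·r² over the negative (resp. positive) branch with the
  **full segment length n** as denominator, so the two indices
  decompose the total risk mass.
* MAGE finds turning points by sign changes of first differences after
  collapsing plateaus; amplitudes are measured between consecutive
  alternating extrema, with the segment endpoints anchoring the first
  and last excursion, and amplitudes strictly greater than k·sd are
  averaged. Both rising and falling excursions count (symmetric
  variant, the default); the classic variant that follows only the
  direction of the first qualifying excursion is available as
  `direction="first"`. A monotone or constant segment, or one with no
  qualifying excursion, has undefined MAGE.
* Undefined values (`mge`, `mgn`, `mage`) propagate as NaN and
  generate **no item** during discretization; no imputation is
  applied.

## Repeated-measures correlation

`rmcorr` is the analysis-of-covariance formulation: both variables are
centred within subject and the common slope association is

r = Σᵢⱼ (x₍ᵢⱼ₎−x̄ᵢ)(y₍ᵢⱼ₎−ȳᵢ) / √(Σ(x−x̄ᵢ)²·Σ(y−ȳᵢ)²),

with df = n_obs − n_subjects − 1 and the p-value from F = r²·df/(1−r²)
on (1, df) degrees of freedom (equivalent to the t parameterisation
for a single slope). Rows with a missing value are dropped pairwise
per metric pair, preserving the maximal n per cell. The reporting
filter keeps cells with raw p < 0.05 and |r| > 0.4, annotated moderate
(≤ 0.6) or strong (> 0.6); no multiple-testing correction is applied
across the 12×12 matrix by default (a Benjamini–Hochberg option
exists), matching the raw-p reporting convention this analysis
follows. Mann-Whitney descriptives use the exact small-sample null
without ties and the tie-corrected normal approximation otherwise,
two-sided, with star bins ns/*/**/***/**** at
0.05/0.01/0.001/0.0001. In the plot-backing table HBGI is additionally
shown ×100 (display only — ranks, and hence the test, are scale
invariant).

## Discretization and mining

Level metrics (mean, min, max, mge, mgn) use the fixed clinical edges
[0, 54, 70, 140, 180, 250] mg/dl labelled severe low / low / normal /
high / severe high; intervals are left-closed/right-open with the last
closed, so 70 mg/dl is "normal" (70 is the exclusive hypoglycemia
threshold) and values above 250 clamp to "severe high" with a warning.
Variability metrics (sd, cv, tir, LBGI, J-index, **and MAGE**) are cut
into empirical tertiles pooled across subjects (a per-subject option
exists); ties on a cut point fall into the lower bin, and duplicate
edges collapse with a warning. MAGE is grouped with the
equal-frequency metrics because its items carry tertile labels even
though it is measured in mg/dl. HBGI is cut into three equal-width
intervals over its **observed** min–max, not a fixed clinical span —
its distribution in normoglycemic cohorts is concentrated near zero,
so fixed clinical edges would leave the upper bins empty.
Discretization is fitted on the same table it transforms (single-cohort
usage; no train/test split).

Each transaction is a sleep-centred day-triple — awake(N−1), sleep(N),
awake(N) — present only when all three segments are complete and the
calendar dates are consecutive. Apriori enumerates itemsets of at most
3 items level-wise with candidate pruning; supports are exact
transaction-count fractions, and the support/confidence/lift threshold
comparisons are performed on exact rationals so boundary values (e.g.
confidence exactly 0.75, lift exactly 2.0) are retained, as inclusive
thresholds require.

## Post-filter

The five constraints are evaluated on exact 2×2 contingency counts
with maximum-likelihood probabilities (counts/n, no smoothing):

* AC and SC are structural (item roles/lags and labels);
* SS is the one-sided (greater) Fisher exact test, kept at p
  **strictly below** 0.05;
* MI is mutual information of the two indicators normalized by the
  smaller marginal entropy, 0·log 0 = 0, degenerate margins giving 0
  by convention, kept **strictly above** 0.3;
* κ is observed agreement corrected by chance agreement, undefined
  (rule fails) when the chance denominator is zero, kept **strictly
  above** 0.3.

Survivors are ranked by lift descending with deterministic tie-breaks
(confidence, support, canonical item order). Redundant rules — longer
antecedents that add nothing over a shorter survivor — are **not**
removed by default, since the five constraints deliberately do not
address redundancy; `prune_redundant=True` enables a dominance-based
pruning pass.

One property of the filter worth knowing: with fewer than ~100
transactions, min-support 0.01 admits single-transaction rules, and a
rule whose antecedent occurs exactly once with a rare extreme
consequent can clear Fisher (p = K/n), MI and κ simultaneously. At the
cohort sizes this package targets (12 subjects × ~2 weeks, ~140
triples) the minimum count is 2 and this artefact class disappears;
analysts running much smaller cohorts should raise `min_supp`.

## Synthetic cohort generator

Each reading is baseline + day-level deviation + circadian term +
meal/dip shape + AR(1) noise, clipped to the 40–400 mg/dl sensor range
and rounded to integers as real sensors report. Specifics:

* **Variance decomposition.** Between-subject baseline sd (default
  4 mg/dl), between-day sd of segment means (9 mg/dl awake and sleep),
  and reading-level AR(1) noise (stationary sd 8 mg/dl awake,
  6 mg/dl in sleep, lag-1 coefficient 0.7). The AR structure makes
  series CGM-like rather than white — MAGE and sd degenerate on white
  noise. Defaults were chosen once to reproduce the awake/sleep ranges
  reported for healthy young adults: awake segment means ≈ 93 ± 10
  mg/dl with within-segment sd ≈ 13, sleep ≈ 85 mg/dl (offset −8) with
  sd ≈ 7.
* **Meals** are raised-cosine bumps (default 3/day at ~8:00, 13:00,
  19:00 with ±30 min jitter, amplitude 35 mg/dl, half-width 60 min),
  giving MAGE-detectable peaks of controllable size. Deterministic
  shape terms are centred within each awake/sleep window so segment
  means are controlled exactly by the configured levels; hypoglycemic
  dips are *not* centred, since a dip should depress the night's mean.
* **Dips** occur with per-night probability (default 0.15) as a
  raised-cosine trough whose floor is awake_mean + sleep_offset −
  depth; nights and days are coupled by correlating the day's awake
  mean deviation with the following night's sleep deviation at
  `coupling_gamma`.
* **Planted rule.** `plant_rule_scenario(config, strength)` raises dip
  depth/frequency so severe-low nights (< 54 mg/dl) occur, and with
  probability `strength` shifts the awake day after a *realized*
  severe-low night down by 30 mg/dl. The shift is large enough that
  the planted days' LBGI separates cleanly from ordinary day-to-day
  variation and lands in the cohort's top tertile, which is the
  guarantee the scenario advertises.
* Everything is deterministic given (seed, subject index); identical
  configs serialize byte-identically.

What the generator does **not** emulate: physiological glucose-insulin
dynamics (no metabolic ODEs), sensor error structure (MARD, compression
artifacts, calibration drift), naps by default (a `nap_prob` flag
exists), or realistic missingness patterns. Passing tests on this
cohort therefore demonstrate that the *statistics and mining machinery*
behave correctly and recover planted structure at realistic effect
sizes and sample sizes — not that any particular physiological claim
holds in real data.

## Problem sizes and numerics

The test suite and the acceptance script use cohorts of 12 subjects ×
14 days (≈ 140 day-triples) for end-to-end checks, 20 independent null
cohorts for the specificity estimate (a null cohort removes *every*
structure shared between awake and sleep segments — coupling, dips and
subject baseline offsets alike, since a subject sitting uniformly low
genuinely couples its awake and sleep items under pooled
discretization), and 25 subjects × 22 days
(500 subject-days) for coupling recovery; miner and interest-measure
oracles run on hundreds of random instances (≤ 12 items × ≤ 200
transactions; 1000 random 2×2 tables). Fisher p-values come from the
hypergeometric distribution via `scipy`; rmcorr p-values use the exact
F tail, with p = 0 at |r| = 1. Apriori candidate counting is
vectorised over the boolean transaction matrix; exact-rational
threshold comparisons use `fractions.Fraction`.

## Known limitations

* Collinearity among GV metrics is not addressed; correlated metrics
  produce clusters of near-duplicate rules and rmcorr cells.
* No multiple-testing correction across the rmcorr matrix or across
  mined rules by default (by design, to match the reporting convention
  of the analysis this package operationalises).
* Pooled discretization lets between-subject baseline differences
  induce genuine cross-segment associations; with marked subject
  heterogeneity, per-subject tertiles (`equal_frequency` per subject)
  are the appropriate variant.
* The day-assignment convention (offset date) differs from
  midnight-split conventions in parts of the CGM literature; profiles
  are not directly comparable across conventions.
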