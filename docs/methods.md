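# Methods

## Model and assumptions

A case is a questionnaire profile (six mean scores in [0, 3]: drive,
thoroughness, opportunity; rejection, inaction, insouciance) plus a sparse
vector of content-analysis category counts. Two further scales
(threat-alert, obstacle) are carried in the data model but excluded from all
rules, since they can accompany both approach and avoidance. Scores are
accepted as already-aggregated scale means; item-level scoring of the
underlying 65-item questionnaire is out of scope.

The classifier is a fixed decision procedure, not a learned model:

1. a per-scale *expression* predicate (score passes its threshold) induces
   the coarse partition approach / evasive / ambivalent / unclassifiable;
2. within the approach group, absence of the extreme-situation category
   (F6) together with a drive/thoroughness profile maximum routes to
   driven-or-maximal, anything else (including an opportunity advantage of
   0.01) to optimal;
3. driven vs maximal is decided purely from markup, by weighted dictionary
   sums S₁ vs S₂.

Two comparison conventions coexist deliberately: default thresholds are
inclusive ("1.5 and higher"), calibrated thresholds strict ("greater
than"). Each threshold therefore carries an explicit inclusivity flag, with
two presets: `baseline` (all six at 1.5, inclusive) and `refined`
(thoroughness 1.65 and insouciance 1.85, both strict; others baseline).

Tie-breaks are explicit and tested: at rule 2, opportunity equal to
max(drive, thoroughness) stays driven-or-maximal (the optimal type requires
a strict advantage); at rule 3, S₁ = S₂ goes to maximal. Markup values are
counts (continuous counting); binary presence/absence coding is the special
case count ∈ {0, 1}. Unknown markup codes are rejected by default; a
permissive mode drops them with a logged warning.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| thresholds | `refined` preset | per-scale expression boundary + inclusivity |
| extreme code | `F6` | markup category vetoing the driven/maximal branch |
| dictionaries | packaged 16-entry example | weighted (1–3) code lists for rule 3 |
| grid | 1.0–2.1, step 0.05 | candidate thresholds for calibration (23 points/scale) |
| holdout | 4:1 split × 500 reps | accuracy protocol for all ML numbers |
| tree depth | ≤ 4 | capacity cap of the default decision-tree learner |

The packaged dictionaries are a **synthetic stand-in**: the study's
subcategory lists are unpublished, so only the five documented codes (A1,
1B9, C6, F6, 1D4) carry real semantics; the rest are placeholders completing
the 16-subcategory, weight-1–3 scheme. F6 appears in Dictionary 2 with the
minimum weight but is inert, because rule 3 only runs when F6 = 0.
Likewise the default 187-code registry is a systematic synthetic code list
containing the five documented codes.

## Threshold calibration

Calibration maximizes agreement with expert labels over the grid, either
exhaustively over a chosen subset of scales (refused above 4 scales without
an explicit override; 23⁶ ≈ 1.5·10⁸ candidates) or by cyclic coordinate
descent over all six. It is unknown whether the original search was joint
over all six scales; both strategies are provided, and on objectives that
factorize across scales (approach expression driven by one scale, avoidance
by another) they provably agree — a constructed test covers this.

Design choices:

* searched thresholds are applied strictly (a calibrated boundary means
  "greater than"); fixed scales keep 1.5 inclusive. At 1.5 the two
  conventions differ only on scores exactly equal to 1.5, a measure-zero
  event for continuous scores;
* the default objective is coarse (rule-1 three-way) agreement; full-pipeline
  agreement is available by flag;
* an unclassifiable prediction counts as a mismatch and the denominator is
  all labeled cases — excluding unclassified predictions would reward
  degenerate high thresholds;
* ties between equally good candidate vectors break toward the
  lexicographically smallest vector in canonical scale order, making reruns
  bit-identical.

## ML benchmark protocol

All accuracies are means over repeated random 4:1 holdout splits (500 by
default), the split sequence fully determined by one seed; learner clones
are seeded from the same stream, so every number is bit-stable under a fixed
seed. A split whose training part is single-class is resampled and logged.
Greedy sequential forward selection scores every remaining candidate feature
under the same split seed per step (ties to the earlier candidate). Note
that forcing k additions does not guarantee a monotone score path — the
recorded guarantee is that each step's score is the maximum over candidates
at that step.

Sequential separation trains three models: {1,2,3 merged} vs 4 vs 5, then
{1,2} vs 3 on approach cases, then 1 vs 2. By default the later steps train
on expert-labeled subpopulations and predictions are composed at inference;
a cascade flag instead restricts later training to cases step 1 itself
routes into the approach group. The cumulative accuracy is trace/total of
the composed confusion matrix accumulated over holdout repetitions — this
identity is asserted rather than any per-step bound, because steps act on
nested subpopulations.

## Synthetic data generator

The generator emulates the per-type structure qualitatively: truncated
normal scale scores around type-consistent means (e.g. driven: drive 2.5,
avoidance means ≈ 0.8; evasive: approach means ≈ 0.9, rejection 2.3), a
common sd (default 0.35), Poisson markup counts at per-type rates
(driven-heavy A1, maximal-heavy 1B9/C6, optimal-heavy 1D4), and a per-type
F6 emission probability that is identically zero for types 1 and 2, whose
situations are by definition non-extreme. The default mixture reproduces
the study counts (67, 89, 139, 245, 60; total 600). The published per-type
descriptive statistics are unavailable, so no distributional fidelity to
the real sample is claimed — the defaults were chosen once from the
qualitative definitions and are fully config-overridable.

In region-enforced mode (default), rejection sampling (capped at 1,000
attempts, failing loudly with the offending type named) guarantees the rule
engine recovers the generating label exactly, with a margin (default 1) on
|S₁ − S₂| for types 1/2 to keep cases off the rule-3 tie boundary. This is
what the 100%-recovery property demonstrates: internal consistency of
generator and rules — not classifier performance on real data, where mixed
types, expert reliance on descriptions, and near-threshold scores produce
the disagreement patterns the confusion-matrix module quantifies. With
enforcement off, recovery degrades monotonically as sd grows (tested at
three noise levels).

## Numerical conventions and degenerate inputs

Internal accuracy arithmetic is float on exact integer counts; rounding is
half-up and happens only at reporting time (overall accuracy to 2 decimals,
per-class to 1). Cases the algorithm leaves unclassified are tabulated in a
separate confusion-matrix column and excluded from accuracy denominators,
mirroring how expert-untyped cases are excluded from the sample. Empty
expert classes yield NaN per-class accuracy; an all-empty matrix makes
overall accuracy an error rather than 0. Scale scores outside [0, 3],
negative counts, duplicate case ids, dictionary weights outside {1, 2, 3}
and overlapping dictionaries all fail fast with the offending row/column or
code named.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes: the
full 600-case mixture for rule-engine recovery, a ~100-case mixture for
protocol tests, 60–500 holdout repetitions, 15–25 repetitions inside
selection loops, and the 4⁶ = 4096-profile grid for the rule-1 oracle.
These sizes make every number reproducible in seconds while leaving the
statistical conclusions (recovery, monotone degradation, chance-level
calibration) unchanged at larger settings.

## Known limitations

* The dictionaries, registry and generator moments are synthetic stand-ins;
  conclusions about the real instrument require the original coding scheme.
* Small-sample holdout on label-independent data is slightly pessimistic
  (class-imbalance anticorrelation between unstratified train and test
  splits), so the null-calibration value scatters around, and a little
  below, 0.5 across datasets.
* A depth-4 tree cannot represent the "any of three scales expressed"
  predicates exactly, so even noise-free synthetic data yields sequential-
  separation accuracy slightly below 1.
* The rule-2 comparison of scales to each other means labels near an
  approach-scale tie are sensitive to arbitrarily small perturbations; only
  the coarse class enjoys the ε-stability guarantee.
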