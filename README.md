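# dltclassify

Typing the perception of **difficult life tasks** (DLTs) — rule-based and
machine-learning classification of questionnaire profiles combined with
content-analysis markup.

## The problem

When people describe a current difficult life task — a situation with a
significant goal and some subjective control — their perception of it can be
typed along the approach–avoidance axis. Respondents rate the task on the
"Types of Orientations in Difficult Situations" questionnaire (TODS); six of
its scales drive the typing: three **approach** orientations (*drive,
thoroughness, opportunity*) and three **avoidance** orientations (*rejection,
inaction, insouciance*), each a mean score on a 0–3 Likert-derived scale. The
free-text description of the task is content-coded into a sparse vector of
category mention counts (the **markup**; e.g. `F6` = threat to life/health,
`A1` = positive intense emotions, `1B9` = necessity).

The package implements a verifiable classifier that explicates the expert
psychologist's decision procedure as three rules, assigning each case to one
of five types: **1 driven, 2 maximal, 3 optimal** (the approach subtypes),
**4 ambivalent** (approach and avoidance combined), **5 evasive** (avoidance
only). It is written for quantitative psychologists and computational
behavioral scientists who want an auditable alternative to black-box
classification of coping/perception profiles.

## The algorithm

A scale is *expressed* when its score passes a threshold: the baseline
convention is score ≥ 1.5 (the scale midpoint); the calibrated preset uses
strict thresholds thoroughness > 1.65 and insouciance > 1.85, the rest at 1.5.
Writing A for the set of expressed approach scales and V for expressed
avoidance scales:

1. **Rule 1 (coarse):** A ≠ ∅, V = ∅ → approach group (types 1–3);
   V ≠ ∅, A = ∅ → type 5; both nonempty → type 4; both empty →
   unclassifiable.
2. **Rule 2 (approach split):** if F6 = 0 and
   max(drive, thoroughness) ≥ opportunity → types 1/2; otherwise (a strict
   opportunity advantage, even by 0.01, or any F6 mention) → type 3.
3. **Rule 3 (driven vs maximal):** with disjoint weighted dictionaries D₁, D₂
   (weights 1–3), compute Sₖ = Σ_{(c,w)∈Dₖ} w·count(c); type 1 iff S₁ > S₂,
   else type 2.

Around the rule engine the package provides threshold calibration by grid
search (1.0–2.1 in steps of 0.05) against expert labels, the
repeated-holdout (4:1 × 500) machine-learning benchmark protocol with
sequential forward feature selection and three-step sequential class
separation ({1,2,3} vs 4 vs 5, then {1,2} vs 3, then 1 vs 2), confusion-matrix
evaluation, and a synthetic-case generator so everything is testable without
the original study sample. The main entry points are scikit-learn style
estimators: `RuleBasedTypeClassifier`, `ThresholdCalibrator`,
`SequentialSeparationClassifier`.

## Worked example

Simulate a noisy sample at the study's per-type mixture (67, 89, 139, 245,
60), then score the rule engine against the generating labels:

```bash
$ dltclassify simulate --out dlt_cases.csv --seed 42 --sd 0.6 --no-enforce
wrote 600 cases to dlt_cases.csv
$ dltclassify evaluate --cases dlt_cases.csv
{
  "provenance": "dltclassify 0.1.0; preset=refined",
  "overall_accuracy_pct": 71.72,
  "per_class_accuracy_pct": [53.8, 61.8, 48.9, 95.1, 62.1],
  "row_totals": [67, 89, 139, 245, 60],
  "total_cases": 600,
  "total_classified": 594,
  "unclassified_predictions": 6,
  "expert_unclassified": 0
}
overall accuracy: 71.72%
```

At scale-score noise sd = 0.6 the rules recover 71.72% of the generating
labels; the ambivalent type is easiest (95.1%) because any co-expression of
approach and avoidance suffices, while the approach subtypes confuse each
other — the same qualitative pattern the expert-agreement study reports. Six
cases expressed no orientation at all and are excluded from the denominator
as unclassifiable. With `--sd 0.35` and region enforcement on (the default),
recovery is exactly 100% — the generator then guarantees each case lies
inside its type's rule region.

Evaluating a published 5×5 agreement table directly:

```bash
$ dltclassify evaluate --matrix table.csv
...
overall accuracy: 77.17%
```

The same pieces are available as a library:

```python
from dltclassify import RuleBasedTypeClassifier, generate_dataset
from dltclassify.io import cases_to_frame, expert_labels

cases = generate_dataset(seed=1)                 # 600 labeled synthetic cases
clf = RuleBasedTypeClassifier(thresholds="refined").fit(cases)
labels = clf.predict(cases)                      # ints 1-5, 0 = unclassifiable
(labels == expert_labels(cases)).mean()          # 1.0 in region-enforced mode
```

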