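"""Threshold calibration by grid search."""

import itertools

import numpy as np
import pytest

from dltclassify.calibrate import GridSpec, ThresholdCalibrator, grid_search
from dltclassify.core import (
    CLASSIFICATION_SCALES,
    Case,
    ConfigError,
    ScaleScores,
    ThresholdConfig,
    TypeLabel,
)
from dltclassify.io import cases_to_frame, expert_labels
from dltclassify.rules import CoarseClass, rule1_coarse
from dltclassify.synth import TypeGenConfig, generate_dataset

TWO_SCALES = ("thoroughness", "insouciance")


def make_case(i, thoroughness, insouciance, label) -> Case:
    values = {s: 1.0 for s in CLASSIFICATION_SCALES}
    values["thoroughness"] = thoroughness
    values["insouciance"] = insouciance
    return Case(f"c{i}", ScaleScores(**values), expert_label=label)


def implanted_dataset() -> list[Case]:
    """Labels flip exactly at thoroughness 1.65 and insouciance 1.85 (strict).

    All other scales sit at 1.0, so approach expression is decided by
    thoroughness alone and avoidance by insouciance alone.  The cells where
    neither is expressed are omitted (such profiles carry no expert type).
    """
    thor_values = [1.2, 1.55, 1.65, 1.70, 1.9, 2.05]
    insou_values = [1.1, 1.6, 1.85, 1.90, 2.0]
    cases = []
    i = 0
    for t, v in itertools.product(thor_values, insou_values):
        expressed_t = t > 1.65
        expressed_v = v > 1.85
        if not expressed_t and not expressed_v:
            continue
        label = 3 if expressed_t and not expressed_v else (5 if expressed_v and not expressed_t else 4)
        i += 1
        cases.append(make_case(i, t, v, label))
    return cases


def oracle_pair_objective(cases, t_thor, t_insou) -> float:
    """Independent evaluation of the coarse objective for one candidate pair."""
    hits = 0
    for c in cases:
        a = c.scales.thoroughness > t_thor  # searched => strict
        v = c.scales.insouciance > t_insou
        pred = "A" if a and not v else ("E" if v and not a else ("M" if a and v else "U"))
        truth = {3: "A", 4: "M", 5: "E"}[int(c.expert_label)]
        hits += pred == truth
    return hits / len(cases)


class TestGridSearch:
    def test_single_point_grid_returns_only_candidate(self):
        cases = implanted_dataset()
        spec = GridSpec(lower=1.5, upper=1.5, scales_to_search=CLASSIFICATION_SCALES)
        best, score = grid_search(cases, spec, allow_large=True)
        assert all(e.threshold == 1.5 for _, e in best.items())
        # the achieved score equals the independently computed agreement
        assert score == pytest.approx(oracle_pair_objective(cases, 1.5, 1.5))

    def test_recovers_implanted_thresholds_exactly(self):
        cases = implanted_dataset()
        spec = GridSpec(scales_to_search=TWO_SCALES)
        points = spec.points()
        assert 1.65 in points and 1.85 in points and len(points) == 23

        # oracle: direct evaluation of all 23x23 candidate pairs
        scored = {
            (t, v): oracle_pair_objective(cases, t, v)
            for t, v in itertools.product(points, points)
        }
        perfect = sorted(pair for pair, s in scored.items() if s == 1.0)
        assert perfect[0] == (1.65, 1.85)

        best, score = grid_search(cases, spec)
        assert score == 1.0
        assert best["thoroughness"].threshold == 1.65 and not best["thoroughness"].inclusive
        assert best["insouciance"].threshold == 1.85 and not best["insouciance"].inclusive
        # non-searched scales keep the fixed inclusive midpoint
        assert best["drive"].threshold == 1.5 and best["drive"].inclusive

    def test_flat_objective_when_labels_ignore_thresholds(self):
        # every score above the whole grid: the coarse class is ambivalent for
        # any candidate, so the objective equals the majority fraction everywhere
        values = {s: 2.5 for s in CLASSIFICATION_SCALES}
        cases = [
            Case(f"c{i}", ScaleScores(**values), expert_label=4 if i < 12 else 1)
            for i in range(20)
        ]
        spec = GridSpec(scales_to_search=TWO_SCALES)
        scored = {
            pair: oracle_flat(cases, pair) for pair in itertools.product(spec.points(), repeat=2)
        }
        assert set(scored.values()) == {0.6}
        _, score = grid_search(cases, spec)
        assert score == pytest.approx(0.6)

    def test_best_score_dominates_baseline_when_on_grid(self):
        cfg = TypeGenConfig.default(sd=0.8, enforce_region=False)
        cases = generate_dataset(cfg, seed=5)
        baseline = ThresholdConfig.baseline()
        coarse_map = {1: "A", 2: "A", 3: "A", 4: "M", 5: "E"}
        hits = 0
        for c in cases:
            coarse = rule1_coarse(c.scales, baseline)
            pred = {
                CoarseClass.APPROACH: "A",
                CoarseClass.AMBIVALENT: "M",
                CoarseClass.EVASIVE: "E",
                CoarseClass.UNCLASSIFIED: "U",
            }[coarse]
            hits += pred == coarse_map[int(c.expert_label)]
        baseline_score = hits / len(cases)
        _, best_score = grid_search(cases, GridSpec(scales_to_search=TWO_SCALES))
        assert best_score >= baseline_score

    def test_coordinate_descent_agrees_on_separable_objective(self):
        cases = implanted_dataset()
        spec = GridSpec(scales_to_search=TWO_SCALES)
        ex_cfg, ex_score = grid_search(cases, spec, strategy="exhaustive")
        cd_cfg, cd_score = grid_search(cases, spec, strategy="coordinate_descent")
        assert ex_score == cd_score == 1.0
        for scale in TWO_SCALES:
            assert ex_cfg[scale] == cd_cfg[scale]

    def test_deterministic_rerun(self):
        cfg = TypeGenConfig.default(sd=0.6, enforce_region=False)
        cases = generate_dataset(cfg, seed=9)
        spec = GridSpec(scales_to_search=TWO_SCALES)
        first = grid_search(cases, spec)
        second = grid_search(cases, spec)
        assert first[1] == second[1]
        assert all(first[0][s] == second[0][s] for s in CLASSIFICATION_SCALES)

    def test_exhaustive_refuses_large_search(self):
        cases = implanted_dataset()
        with pytest.raises(ConfigError, match="refused"):
            grid_search(cases, GridSpec(scales_to_search=CLASSIFICATION_SCALES[:5]))

    def test_requires_labeled_cases(self):
        values = {s: 2.0 for s in CLASSIFICATION_SCALES}
        cases = [Case("c1", ScaleScores(**values))]
        with pytest.raises(ValueError, match="label"):
            grid_search(cases, GridSpec(scales_to_search=TWO_SCALES))


def oracle_flat(cases, pair) -> float:
    t, v = pair
    hits = 0
    for c in cases:
        # all six scores above both candidates, so always ambivalent
        hits += int(c.expert_label) == 4
    return hits / len(cases)


class TestThresholdCalibrator:
    def test_fit_exposes_config_and_score(self):
        cases = implanted_dataset()
        y = expert_labels(cases)
        est = ThresholdCalibrator(grid=GridSpec(scales_to_search=TWO_SCALES))
        est.fit(cases, y)
        assert est.best_score_ == 1.0
        assert est.best_config_["thoroughness"].threshold == 1.65
        predictions = est.predict(cases)
        assert set(predictions) <= {0, 1, 2, 3, 4, 5}

    def test_accepts_dataframe_input(self):
        cases = implanted_dataset()
        df = cases_to_frame(cases).drop(columns=["expert_label"])
        y = expert_labels(cases)
        est = ThresholdCalibrator(grid=GridSpec(scales_to_search=TWO_SCALES)).fit(df, y)
        assert est.best_score_ == 1.0
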