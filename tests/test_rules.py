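"""The three decision rules and their composition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dltclassify.core import (
    CLASSIFICATION_SCALES,
    Case,
    ConfigError,
    MarkupVector,
    ScaleScores,
    ThresholdConfig,
    TypeLabel,
    WeightedDictionary,
    default_registry,
)
from dltclassify.io import cases_to_frame
from dltclassify.rules import (
    CoarseClass,
    Rule2Result,
    RuleBasedTypeClassifier,
    classify_case,
    default_dictionaries,
    rule1_coarse,
    rule2_approach_split,
    rule3_dictionary_split,
)

scores_st = st.floats(0.0, 3.0, allow_nan=False)


def make_scales(**overrides) -> ScaleScores:
    values = {s: 1.0 for s in CLASSIFICATION_SCALES}
    values.update(overrides)
    return ScaleScores(**values)


def make_case(markup=None, **scales) -> Case:
    return Case("c", make_scales(**scales), MarkupVector(markup or {}))


class TestRule1:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({"drive": 2.0}, CoarseClass.APPROACH),
            ({"rejection": 2.0}, CoarseClass.EVASIVE),
            ({}, CoarseClass.UNCLASSIFIED),
            ({"drive": 2.0, "rejection": 2.0}, CoarseClass.AMBIVALENT),
        ],
    )
    def test_four_branches_baseline(self, overrides, expected):
        assert rule1_coarse(make_scales(**overrides), ThresholdConfig.baseline()) is expected

    @given(values=st.lists(scores_st, min_size=6, max_size=6))
    def test_partition_exactly_one_coarse_class(self, values):
        scales = ScaleScores(**dict(zip(CLASSIFICATION_SCALES, values)))
        for config in (ThresholdConfig.baseline(), ThresholdConfig.refined()):
            assert rule1_coarse(scales, config) in CoarseClass
            assert rule1_coarse(scales, config) is rule1_coarse(scales, config)


class TestRule2:
    def test_drive_maximum_without_extreme_category(self):
        case = make_case(drive=2.5, thoroughness=2.0, opportunity=2.0)
        assert rule2_approach_split(case.scales, case.markup) is Rule2Result.DRIVEN_OR_MAXIMAL

    def test_slight_opportunity_advantage_is_optimal(self):
        # an advantage of just 0.01 on the opportunity scale flips the case
        case = make_case(opportunity=2.01, drive=2.0, thoroughness=1.9)
        assert rule2_approach_split(case.scales, case.markup) is Rule2Result.OPTIMAL

    def test_extreme_category_vetoes_driven_maximal(self):
        case = make_case({"F6": 1}, drive=2.5, opportunity=1.6)
        assert rule2_approach_split(case.scales, case.markup) is Rule2Result.OPTIMAL

    def test_opportunity_tie_stays_driven_or_maximal(self):
        case = make_case(drive=2.0, thoroughness=1.5, opportunity=2.0)
        assert rule2_approach_split(case.scales, case.markup) is Rule2Result.DRIVEN_OR_MAXIMAL

    def test_unknown_extreme_code_is_config_error(self):
        case = make_case(drive=2.0)
        with pytest.raises(ConfigError):
            rule2_approach_split(case.scales, case.markup, extreme_code="NOPE")


class TestRule3:
    d1 = WeightedDictionary("d1", (("A1", 3),))
    d2 = WeightedDictionary("d2", (("1B9", 3),))

    def test_weighted_sums_forced_arithmetic(self):
        markup = MarkupVector({"A1": 2, "1B9": 1})
        assert rule3_dictionary_split(markup, self.d1, self.d2) is TypeLabel.DRIVEN

    def test_tie_goes_to_maximal(self):
        assert rule3_dictionary_split(MarkupVector({}), self.d1, self.d2) is TypeLabel.MAXIMAL

    def test_lower_sum_is_maximal(self):
        d1 = WeightedDictionary("d1", (("A1", 1),))
        d2 = WeightedDictionary("d2", (("1B9", 2),))
        markup = MarkupVector({"A1": 1, "1B9": 1})
        assert rule3_dictionary_split(markup, d1, d2) is TypeLabel.MAXIMAL

    def test_overlapping_dictionaries_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            rule3_dictionary_split(MarkupVector({}), self.d1, WeightedDictionary("d2", (("A1", 1),)))

    @given(count=st.integers(0, 10))
    def test_invariant_to_codes_outside_both_dictionaries(self, count):
        d1, d2 = default_dictionaries()
        outside = sorted(default_registry() - d1.codes - d2.codes)[:3]
        base = rule3_dictionary_split(MarkupVector({"A1": 1}), d1, d2)
        noisy = MarkupVector({"A1": 1, **{c: count for c in outside}})
        assert rule3_dictionary_split(noisy, d1, d2) is base


class TestClassifyCase:
    def test_flat_profile_is_unclassified(self):
        assert classify_case(make_case()) is TypeLabel.UNCLASSIFIED

    def test_pure_avoidance_is_evasive(self):
        case = make_case(rejection=2.0, inaction=2.0)
        assert classify_case(case) is TypeLabel.EVASIVE

    def test_composition_reaches_driven(self):
        d1 = WeightedDictionary("d1", (("A1", 3),))
        d2 = WeightedDictionary("d2", (("1B9", 3),))
        case = make_case({"A1": 2}, drive=2.5, opportunity=1.6)
        assert classify_case(case, dictionaries=(d1, d2)) is TypeLabel.DRIVEN

    @given(
        values=st.lists(scores_st, min_size=6, max_size=6),
        a1=st.integers(0, 5),
        f6=st.integers(0, 2),
    )
    def test_partition_and_determinism(self, values, a1, f6):
        case = Case(
            "c",
            ScaleScores(**dict(zip(CLASSIFICATION_SCALES, values))),
            MarkupVector({"A1": a1, "F6": f6}),
        )
        label = classify_case(case)
        assert label in TypeLabel
        assert classify_case(case) is label

    @given(
        data=st.lists(
            st.floats(0.0, 3.0, allow_nan=False).filter(lambda x: abs(x - 1.5) > 0.05),
            min_size=6,
            max_size=6,
        ),
        signs=st.lists(st.sampled_from([-1.0, 1.0]), min_size=6, max_size=6),
        eps=st.floats(0.0, 0.04),
    )
    def test_coarse_class_stable_under_small_perturbation_baseline(self, data, signs, eps):
        # scores bounded away from the 1.5 threshold keep their coarse class
        # under perturbations smaller than the gap (the fine label is NOT
        # protected: rule 2 compares approach scales to each other, so a tie
        # between opportunity and drive/thoroughness can flip under any eps)
        base = ThresholdConfig.baseline()
        scales = ScaleScores(**dict(zip(CLASSIFICATION_SCALES, data)))
        # eps < each score's distance to 1.5, so no score changes side
        perturbed_values = [
            float(np.clip(v + s * eps, 0.0, 3.0)) for v, s in zip(data, signs)
        ]
        perturbed = ScaleScores(**dict(zip(CLASSIFICATION_SCALES, perturbed_values)))
        assert rule1_coarse(scales, base) is rule1_coarse(perturbed, base)


class TestRuleBasedEstimator:
    def test_predict_matches_function_composition(self, small_noise_free):
        clf = RuleBasedTypeClassifier(thresholds="refined").fit(small_noise_free)
        from_cases = clf.predict(small_noise_free)
        df = cases_to_frame(small_noise_free)
        from_frame = clf.predict(df)
        expected = np.array([int(classify_case(c)) for c in small_noise_free])
        assert (from_cases == expected).all()
        assert (from_frame == expected).all()

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        clf = RuleBasedTypeClassifier(thresholds="baseline", extreme_code="F6")
        cloned = clone(clf)
        assert cloned.get_params()["thresholds"] == "baseline"
        cloned.set_params(thresholds="refined")
        assert cloned.thresholds == "refined"
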