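"""The three decision rules and their composition into the final classifier.

The classifier explicates the expert psychologist's decision procedure as
three verifiable rules applied in sequence (a hand-built decision tree):

Rule 1 (coarse split on the questionnaire profile alone)
    * some approach orientation expressed, no avoidance -> approach group
      (types 1-3);
    * some avoidance expressed, no approach -> evasive (type 5);
    * both expressed -> ambivalent (type 4);
    * neither expressed -> unclassifiable.

Rule 2 (within the approach group)
    If the extreme-situation markup category (F6, threat to life/health) is
    absent *and* the profile maximum among the approach scales falls on drive
    and/or thoroughness, the case is driven-or-maximal (types 1/2); otherwise
    -- a strict advantage of the opportunity scale, or any F6 mention -- it is
    optimal (type 3).

Rule 3 (driven vs maximal, markup only)
    Weighted sums of the case's markup counts over two disjoint weighted
    dictionaries; driven iff the Dictionary-1 sum strictly exceeds the
    Dictionary-2 sum, maximal otherwise (ties included).

:class:`RuleBasedTypeClassifier` packages the composition as a scikit-learn
style classifier so it slots into pipelines and model-selection utilities.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import (
    APPROACH_SCALES,
    Case,
    ConfigError,
    MarkupVector,
    ScaleScores,
    ThresholdConfig,
    TypeLabel,
    WeightedDictionary,
    check_disjoint,
    expressed_sets,
)

__all__ = [
    "CoarseClass",
    "Rule2Result",
    "rule1_coarse",
    "rule2_approach_split",
    "rule3_dictionary_split",
    "classify_case",
    "classify_dataset",
    "default_dictionaries",
    "RuleBasedTypeClassifier",
    "DEFAULT_EXTREME_CODE",
]

#: Markup category flagging an extreme situation (threat to life/health).
DEFAULT_EXTREME_CODE = "F6"


class CoarseClass(enum.Enum):
    """Outcome of rule 1: the top-level approach/avoidance partition."""

    APPROACH = "approach"  # types 1-3, merged
    AMBIVALENT = "ambivalent"  # type 4
    EVASIVE = "evasive"  # type 5
    UNCLASSIFIED = "unclassified"


class Rule2Result(enum.Enum):
    DRIVEN_OR_MAXIMAL = "driven_or_maximal"
    OPTIMAL = "optimal"


def rule1_coarse(scales: ScaleScores, config: ThresholdConfig) -> CoarseClass:
    """Coarse split by which orientation families are expressed."""
    approach, avoidance = expressed_sets(scales, config)
    if approach and not avoidance:
        return CoarseClass.APPROACH
    if avoidance and not approach:
        return CoarseClass.EVASIVE
    if approach and avoidance:
        return CoarseClass.AMBIVALENT
    return CoarseClass.UNCLASSIFIED


def rule2_approach_split(
    scales: ScaleScores,
    markup: MarkupVector,
    extreme_code: str = DEFAULT_EXTREME_CODE,
) -> Rule2Result:
    """Separate driven/maximal (types 1/2) from optimal (type 3).

    Driven-or-maximal requires the extreme-situation category to be absent
    and the approach-profile maximum to fall on drive and/or thoroughness.
    A strict opportunity advantage -- even by 0.01 -- or any mention of the
    extreme category routes the case to the optimal type.  A tie between
    opportunity and max(drive, thoroughness) therefore stays
    driven-or-maximal.
    """
    if markup.get(extreme_code) == 0 and max(scales.drive, scales.thoroughness) >= scales.opportunity:
        return Rule2Result.DRIVEN_OR_MAXIMAL
    return Rule2Result.OPTIMAL


def rule3_dictionary_split(
    markup: MarkupVector,
    dict1: WeightedDictionary,
    dict2: WeightedDictionary,
) -> TypeLabel:
    """Separate driven (1) from maximal (2) by weighted dictionary sums.

    Returns DRIVEN iff the Dictionary-1 sum strictly exceeds the
    Dictionary-2 sum; ties go to MAXIMAL.
    """
    check_disjoint(dict1, dict2)
    s1 = dict1.weighted_sum(markup)
    s2 = dict2.weighted_sum(markup)
    return TypeLabel.DRIVEN if s1 > s2 else TypeLabel.MAXIMAL


def classify_case(
    case: Case,
    config: Optional[ThresholdConfig] = None,
    dictionaries: Optional[tuple[WeightedDictionary, WeightedDictionary]] = None,
    extreme_code: str = DEFAULT_EXTREME_CODE,
) -> TypeLabel:
    """Full composition of the three rules for one case.

    Defaults: refined thresholds and the packaged example dictionaries.
    """
    config = config if config is not None else ThresholdConfig.refined()
    dict1, dict2 = dictionaries if dictionaries is not None else default_dictionaries()
    coarse = rule1_coarse(case.scales, config)
    if coarse is CoarseClass.AMBIVALENT:
        return TypeLabel.AMBIVALENT
    if coarse is CoarseClass.EVASIVE:
        return TypeLabel.EVASIVE
    if coarse is CoarseClass.UNCLASSIFIED:
        return TypeLabel.UNCLASSIFIED
    if rule2_approach_split(case.scales, case.markup, extreme_code) is Rule2Result.OPTIMAL:
        return TypeLabel.OPTIMAL
    return rule3_dictionary_split(case.markup, dict1, dict2)


def classify_dataset(
    cases: Iterable[Case],
    config: Optional[ThresholdConfig] = None,
    dictionaries: Optional[tuple[WeightedDictionary, WeightedDictionary]] = None,
    extreme_code: str = DEFAULT_EXTREME_CODE,
) -> list[TypeLabel]:
    return [classify_case(c, config, dictionaries, extreme_code) for c in cases]


# The published subcategory lists (appendix of the source study) are not
# available; these example dictionaries are synthetic stand-ins.  The codes
# with documented semantics are A1 ("positive intense emotions", uniquely
# characterizes the driven type) and 1B9 ("necessity") plus C6 ("need to
# achieve maximum results") for the maximal type.  F6 is listed with the
# minimum weight for completeness but is inert in rule 3, which only runs
# when F6 = 0.  The remaining codes are placeholders filling out the
# 16-subcategory, weight 1-3 scheme the study describes.
_DICT1_ENTRIES = (
    ("A1", 3),   # positive intense emotions
    ("A2", 2),   # placeholder: excitement / energy surge
    ("B3", 2),   # placeholder: self-development
    ("C2", 2),   # placeholder: high results
    ("1D4", 1),  # planful coping (shared approach marker, weakly driven)
    ("D1", 1),
    ("E4", 1),
    ("1A2", 1),
)
_DICT2_ENTRIES = (
    ("1B9", 3),  # necessity
    ("C6", 3),   # need to achieve maximum results
    ("B7", 2),   # placeholder: multitasking
    ("C8", 2),   # placeholder: perfectionist goal
    ("F6", 1),   # threat to life/health; inert (rule 3 requires F6 = 0)
    ("D5", 1),
    ("E6", 1),
    ("1A7", 1),
)


def default_dictionaries() -> tuple[WeightedDictionary, WeightedDictionary]:
    """The packaged example Dictionary 1 (driven) and Dictionary 2 (maximal)."""
    return (
        WeightedDictionary("driven", _DICT1_ENTRIES),
        WeightedDictionary("maximal", _DICT2_ENTRIES),
    )


def _as_cases(X, registry=None) -> list[Case]:
    """Accept a list of Case objects or a canonical-schema DataFrame."""
    if isinstance(X, pd.DataFrame):
        from .io import frame_to_cases

        return frame_to_cases(X, registry=registry)
    cases = list(X)
    if cases and not isinstance(cases[0], Case):
        raise TypeError(
            "X must be a pandas DataFrame with canonical columns or an iterable of Case objects"
        )
    return cases


class RuleBasedTypeClassifier(ClassifierMixin, BaseEstimator):
    """The rule-based five-type classifier as a scikit-learn estimator.

    Parameters
    ----------
    thresholds : str or ThresholdConfig, default "refined"
        Preset name ("baseline" or "refined") or an explicit config.
    dictionaries : pair of WeightedDictionary, optional
        Dictionary 1 (driven) and Dictionary 2 (maximal); defaults to the
        packaged example dictionaries.
    extreme_code : str, default "F6"
        Markup category whose presence vetoes the driven/maximal branch.
    registry : frozenset of str, optional
        Admissible markup codes when X is a DataFrame (default registry
        otherwise).

    The estimator is rule-driven: ``fit`` only validates and freezes the
    configuration (no parameters are learned from ``y``).  ``predict``
    returns integer labels 1-5, with 0 for unclassifiable profiles.
    """

    def __init__(
        self,
        thresholds: Union[str, ThresholdConfig] = "refined",
        dictionaries: Optional[tuple[WeightedDictionary, WeightedDictionary]] = None,
        extreme_code: str = DEFAULT_EXTREME_CODE,
        registry: Optional[frozenset] = None,
    ):
        self.thresholds = thresholds
        self.dictionaries = dictionaries
        self.extreme_code = extreme_code
        self.registry = registry

    def fit(self, X, y=None):
        if isinstance(self.thresholds, str):
            self.thresholds_ = ThresholdConfig.from_preset(self.thresholds)
        else:
            self.thresholds_ = self.thresholds
        d1, d2 = self.dictionaries if self.dictionaries is not None else default_dictionaries()
        check_disjoint(d1, d2)
        self.dict1_, self.dict2_ = d1, d2
        self.classes_ = np.array([int(t) for t in TypeLabel])
        if isinstance(X, pd.DataFrame):
            self.n_features_in_ = X.shape[1]
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            self.fit(X)
        cases = _as_cases(X, registry=self.registry)
        return np.array(
            [
                int(
                    classify_case(
                        c, self.thresholds_, (self.dict1_, self.dict2_), self.extreme_code
                    )
                )
                for c in cases
            ],
            dtype=int,
        )
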