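"""Threshold calibration by search against expert labels.

The expression thresholds of the six scales are free parameters of rule 1.
Calibration searches candidate threshold vectors on a grid (default 1.0 to
2.1 in steps of 0.05, 23 points per scale) and keeps the vector that best
agrees with the expert labels.  Two strategies are provided:

* ``exhaustive`` -- the full Cartesian product over a chosen subset of
  scales (refused above 4 scales unless explicitly overridden; 23**6 is
  about 1.5e8 candidates);
* ``coordinate_descent`` -- cyclic one-scale-at-a-time sweeps over all six
  scales until no sweep improves the objective.

Searched thresholds are applied with *strict* comparison (a calibrated
boundary means "greater than"); non-searched scales keep their fixed value
with the inclusive midpoint convention.  Ties between equally good candidate
vectors break toward the lexicographically smallest vector in canonical scale
order, so a rerun on the same data reproduces the same configuration.

Two objectives are available: ``coarse_accuracy`` scores agreement of the
rule-1 coarse class (approach group / ambivalent / evasive) with the
coarse-grained expert label, and ``full_accuracy`` scores exact agreement of
the full three-rule composition.  An unclassifiable prediction never counts
as a match, and the denominator is all expert-labeled cases; this keeps the
objective from rewarding degenerate high thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import (
    AVOIDANCE_SCALES,
    CLASSIFICATION_SCALES,
    Case,
    ConfigError,
    ThresholdConfig,
    ThresholdEntry,
    TypeLabel,
    WeightedDictionary,
)
from .rules import (
    DEFAULT_EXTREME_CODE,
    Rule2Result,
    RuleBasedTypeClassifier,
    default_dictionaries,
    rule2_approach_split,
    rule3_dictionary_split,
)

__all__ = ["GridSpec", "grid_search", "ThresholdCalibrator"]

_OBJECTIVES = ("coarse_accuracy", "full_accuracy")
_STRATEGIES = ("exhaustive", "coordinate_descent")
MAX_EXHAUSTIVE_SCALES = 4


@dataclass(frozen=True)
class GridSpec:
    """Candidate threshold lattice and search scope.

    ``fixed`` optionally overrides the threshold of non-searched scales
    (default 1.5, inclusive).
    """

    lower: float = 1.0
    upper: float = 2.1
    step: float = 0.05
    scales_to_search: tuple[str, ...] = CLASSIFICATION_SCALES
    fixed: Optional[dict[str, float]] = None
    objective: str = "coarse_accuracy"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ConfigError("grid lower bound exceeds upper bound")
        if self.step <= 0:
            raise ConfigError("grid step must be positive")
        scales = tuple(self.scales_to_search)
        unknown = set(scales) - set(CLASSIFICATION_SCALES)
        if not scales or unknown:
            raise ConfigError(f"scales_to_search must be a nonempty subset of the six scales; unknown={sorted(unknown)}")
        if self.objective not in _OBJECTIVES:
            raise ConfigError(f"objective must be one of {_OBJECTIVES}")
        object.__setattr__(self, "scales_to_search", scales)

    def points(self) -> tuple[float, ...]:
        n = int(np.floor((self.upper - self.lower) / self.step + 1e-9)) + 1
        return tuple(round(self.lower + k * self.step, 10) for k in range(n))


def _prepare(cases: Sequence[Case], spec: GridSpec, dictionaries, extreme_code):
    """Precompute everything the vectorized objective needs.

    Rules 2 and 3 do not depend on the thresholds, so each case's would-be
    approach subtype (1, 2 or 3) is resolved once up front.
    """
    labeled = [c for c in cases if c.expert_label not in (None, TypeLabel.UNCLASSIFIED)]
    if not labeled:
        raise ValueError("threshold calibration requires expert-labeled cases")
    scores = np.array(
        [[c.scales[s] for s in CLASSIFICATION_SCALES] for c in labeled], dtype=float
    )
    expert = np.array([int(c.expert_label) for c in labeled], dtype=int)
    dict1, dict2 = dictionaries
    approach_sub = np.array(
        [
            int(TypeLabel.OPTIMAL)
            if rule2_approach_split(c.scales, c.markup, extreme_code) is Rule2Result.OPTIMAL
            else int(rule3_dictionary_split(c.markup, dict1, dict2))
            for c in labeled
        ],
        dtype=int,
    )
    return scores, expert, approach_sub


def _objective_value(scores, expert, approach_sub, thresholds, strict, objective):
    """Agreement fraction of a candidate threshold vector with expert labels."""
    expressed = np.where(strict, scores > thresholds, scores >= thresholds)
    appr = expressed[:, :3].any(axis=1)
    avoid = expressed[:, 3:].any(axis=1)
    if objective == "coarse_accuracy":
        # coarse codes: 0 = approach group, 1 = ambivalent, 2 = evasive, 3 = none
        pred = np.where(appr & ~avoid, 0, np.where(appr & avoid, 1, np.where(avoid, 2, 3)))
        truth = np.where(expert <= 3, 0, np.where(expert == 4, 1, 2))
        return float(np.mean(pred == truth))
    pred = np.where(
        appr & ~avoid, approach_sub, np.where(appr & avoid, 4, np.where(avoid, 5, 0))
    )
    return float(np.mean(pred == expert))


def _build_config(spec: GridSpec, values: dict[str, float]) -> ThresholdConfig:
    fixed = spec.fixed or {}
    entries = {}
    for scale in CLASSIFICATION_SCALES:
        if scale in values:
            entries[scale] = ThresholdEntry(values[scale], inclusive=False)
        else:
            entries[scale] = ThresholdEntry(fixed.get(scale, 1.5), inclusive=True)
    return ThresholdConfig(entries)


def _vectors(spec: GridSpec, values: dict[str, float]):
    """(thresholds, strict) arrays in canonical scale order for a candidate."""
    fixed = spec.fixed or {}
    t = np.empty(6)
    strict = np.zeros(6, dtype=bool)
    for i, scale in enumerate(CLASSIFICATION_SCALES):
        if scale in values:
            t[i] = values[scale]
            strict[i] = True
        else:
            t[i] = fixed.get(scale, 1.5)
    return t, strict


def grid_search(
    cases: Sequence[Case],
    spec: Optional[GridSpec] = None,
    strategy: str = "exhaustive",
    dictionaries: Optional[tuple[WeightedDictionary, WeightedDictionary]] = None,
    extreme_code: str = DEFAULT_EXTREME_CODE,
    allow_large: bool = False,
    max_sweeps: int = 10,
) -> tuple[ThresholdConfig, float]:
    """Search the threshold grid; return (best config, best agreement fraction)."""
    spec = spec if spec is not None else GridSpec()
    if strategy not in _STRATEGIES:
        raise ConfigError(f"strategy must be one of {_STRATEGIES}")
    dictionaries = dictionaries if dictionaries is not None else default_dictionaries()
    scores, expert, approach_sub = _prepare(cases, spec, dictionaries, extreme_code)
    searched = [s for s in CLASSIFICATION_SCALES if s in spec.scales_to_search]
    points = spec.points()

    def score_of(values: dict[str, float]) -> float:
        t, strict = _vectors(spec, values)
        return _objective_value(scores, expert, approach_sub, t, strict, spec.objective)

    if strategy == "exhaustive":
        if len(searched) > MAX_EXHAUSTIVE_SCALES and not allow_large:
            raise ConfigError(
                f"exhaustive search over {len(searched)} scales "
                f"({len(points)}**{len(searched)} candidates) refused; "
                "pass allow_large=True or use strategy='coordinate_descent'"
            )
        best_values, best_score = None, -1.0
        # lexicographic candidate order + strict improvement = smallest-vector ties
        for combo in itertools.product(points, repeat=len(searched)):
            values = dict(zip(searched, combo))
            val = score_of(values)
            if val > best_score:
                best_values, best_score = values, val
    else:
        start = min(points, key=lambda p: (abs(p - 1.5), p))
        values = {s: start for s in searched}
        best_score = score_of(values)
        for _ in range(max_sweeps):
            improved = False
            for scale in searched:
                cand_best, cand_score = values[scale], best_score
                for p in points:
                    trial = dict(values, **{scale: p})
                    val = score_of(trial)
                    if val > cand_score or (val == cand_score and p < cand_best):
                        cand_best, cand_score = p, val
                if cand_best != values[scale] or cand_score > best_score:
                    values[scale] = cand_best
                    improved = improved or cand_score > best_score
                    best_score = cand_score
            if not improved:
                break
        best_values = values

    return _build_config(spec, best_values), best_score


class ThresholdCalibrator(ClassifierMixin, BaseEstimator):
    """Grid-search threshold calibration wrapped as a scikit-learn estimator.

    ``fit(X, y)`` runs :func:`grid_search` against the expert labels ``y``
    (X may be a canonical-schema DataFrame or a list of Case objects) and
    stores ``best_config_`` / ``best_score_``; ``predict`` applies the
    rule-based classifier under the calibrated thresholds.
    """

    def __init__(
        self,
        grid: Optional[GridSpec] = None,
        strategy: str = "exhaustive",
        dictionaries: Optional[tuple[WeightedDictionary, WeightedDictionary]] = None,
        extreme_code: str = DEFAULT_EXTREME_CODE,
        allow_large: bool = False,
    ):
        self.grid = grid
        self.strategy = strategy
        self.dictionaries = dictionaries
        self.extreme_code = extreme_code
        self.allow_large = allow_large

    def fit(self, X, y):
        from .rules import _as_cases

        cases = _as_cases(X)
        y = np.asarray(y, dtype=int)
        if len(y) != len(cases):
            raise ValueError("X and y length mismatch")
        cases = [
            Case(c.case_id, c.scales, c.markup, TypeLabel(int(label)))
            for c, label in zip(cases, y)
        ]
        self.best_config_, self.best_score_ = grid_search(
            cases,
            self.grid,
            strategy=self.strategy,
            dictionaries=self.dictionaries,
            extreme_code=self.extreme_code,
            allow_large=self.allow_large,
        )
        self.classes_ = np.array([int(t) for t in TypeLabel])
        return self

    def predict(self, X):
        clf = RuleBasedTypeClassifier(
            thresholds=self.best_config_,
            dictionaries=self.dictionaries,
            extreme_code=self.extreme_code,
        ).fit(X)
        return clf.predict(X)
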