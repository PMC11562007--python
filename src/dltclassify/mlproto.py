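"""Machine-learning baseline protocol: repeated holdout, forward feature
selection, and three-step sequential class separation.

The protocol mirrors how the rule-based classifier was benchmarked against
standard learners:

* accuracy is estimated by randomly splitting the sample into training and
  testing parts in a 4:1 ratio, repeating the split (500 times by default)
  and averaging test accuracy;
* features are chosen by greedy sequential forward selection under that
  same protocol (the benchmark settled on 11 features: the six scales plus
  five markup categories);
* instead of one five-way decision, classes are separated sequentially --
  first {1,2,3 merged} vs 4 vs 5, then {1,2} vs 3 within the approach
  group, then 1 vs 2 -- because type 5 and the approach group are close to
  linearly separable in the avoidance/approach score spaces.

Learners are injected as scikit-learn estimators (anything with
``fit``/``predict``); no learning algorithm is defined here.  The default
learner is a depth-capped decision tree (maximum depth 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.tree import DecisionTreeClassifier

from .evaluate import build_confusion

__all__ = [
    "default_learner",
    "repeated_holdout_accuracy",
    "sequential_forward_selection",
    "SelectionResult",
    "SequentialSeparationClassifier",
    "sequential_separation",
    "SeparationResult",
]

logger = logging.getLogger(__name__)

#: Merged step-1 label for the approach group (types 1-3).
APPROACH_MERGED = 0
_MAX_RESAMPLE = 100


def default_learner() -> DecisionTreeClassifier:
    """Decision tree with the protocol's depth cap of 4."""
    return DecisionTreeClassifier(max_depth=4)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _fresh(learner, rng) -> BaseEstimator:
    """Clone the learner, seeding it from the protocol RNG when possible."""
    model = clone(learner)
    if "random_state" in model.get_params():
        model.set_params(random_state=int(rng.integers(2**31)))
    return model


def repeated_holdout_accuracy(
    X,
    y,
    learner: Optional[BaseEstimator] = None,
    test_fraction: float = 0.2,
    reps: int = 500,
    random_state: Optional[int] = None,
) -> float:
    """Mean test accuracy over repeated random 4:1 train/test splits.

    The split sequence is fully determined by ``random_state``.  A split
    whose training part contains a single class is resampled (logged).
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("repeated holdout requires at least two classes")
    n = len(y)
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        raise ValueError("test fraction leaves no training data")
    rng = np.random.default_rng(random_state)
    accuracies = np.empty(reps)
    for rep in range(reps):
        for attempt in range(_MAX_RESAMPLE):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if len(np.unique(y[train_idx])) >= 2:
                break
            logger.warning("single-class training split resampled (rep %d)", rep)
        else:
            raise RuntimeError("could not draw a training split with two classes")
        model = _fresh(learner if learner is not None else default_learner(), rng)
        model.fit(X[train_idx], y[train_idx])
        accuracies[rep] = np.mean(model.predict(X[test_idx]) == y[test_idx])
    return float(accuracies.mean())


@dataclass(frozen=True)
class SelectionResult:
    """Greedy forward-selection path: chosen features in order of addition
    and the protocol score recorded when each was added."""

    features: tuple[str, ...]
    path_scores: tuple[float, ...]


def sequential_forward_selection(
    X: pd.DataFrame,
    y,
    learner: Optional[BaseEstimator] = None,
    k: int = 11,
    reps: int = 25,
    test_fraction: float = 0.2,
    random_state: Optional[int] = None,
) -> SelectionResult:
    """Greedy forward selection of ``k`` features under the holdout protocol.

    At each step every remaining candidate is scored (with the same split
    seed, so candidates face identical splits) and the best is added; ties
    break toward the earlier candidate in column order.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("sequential_forward_selection requires a DataFrame with named columns")
    candidates = list(X.columns)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate features")
    ss = np.random.SeedSequence(random_state)
    step_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(k)]
    selected: list[str] = []
    path_scores: list[float] = []
    for step in range(k):
        best_feature, best_score = None, -1.0
        for feature in candidates:
            if feature in selected:
                continue
            score = repeated_holdout_accuracy(
                X[selected + [feature]],
                y,
                learner=learner,
                test_fraction=test_fraction,
                reps=reps,
                random_state=step_seeds[step],
            )
            if score > best_score:
                best_feature, best_score = feature, score
        selected.append(best_feature)
        path_scores.append(best_score)
    return SelectionResult(tuple(selected), tuple(path_scores))


class SequentialSeparationClassifier(ClassifierMixin, BaseEstimator):
    """Three-step sequential separation of the five types.

    Step 1 trains a 3-way model on {1,2,3 merged} vs 4 vs 5; step 2 a
    binary {1,2 merged} vs 3 model on the approach cases; step 3 a binary
    1 vs 2 model.  Prediction composes the steps.  By default the later
    steps train on expert-labeled subpopulations; with ``cascade=True``
    they train on the cases step 1 itself routes into the approach group
    (intersected with the expert approach cases, which alone carry the
    fine-grained labels the later steps need).

    A step whose training subpopulation is empty is skipped with a warning;
    its branch then cannot occur at prediction time on data from the same
    label universe.
    """

    def __init__(
        self,
        base_estimator: Optional[BaseEstimator] = None,
        cascade: bool = False,
        random_state: Optional[int] = None,
    ):
        self.base_estimator = base_estimator
        self.cascade = cascade
        self.random_state = random_state

    def _make(self, rng):
        proto = self.base_estimator if self.base_estimator is not None else default_learner()
        return _fresh(proto, rng)

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=int)
        if not np.isin(y, [1, 2, 3, 4, 5]).all():
            raise ValueError("sequential separation requires labels in 1..5")
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]

        y3 = np.where(y <= 3, APPROACH_MERGED, y)
        self.model1_ = self._make(rng).fit(X, y3)

        approach = y <= 3
        if self.cascade:
            approach = approach & (self.model1_.predict(X) == APPROACH_MERGED)
        if approach.any():
            y2 = np.where(y[approach] <= 2, APPROACH_MERGED, 3)
            self.model2_ = self._make(rng).fit(X[approach], y2)
        else:
            logger.warning("step 2 skipped: no approach-group training cases")
            self.model2_ = None

        first_two = approach & (y <= 2)
        if first_two.any():
            self.model3_ = self._make(rng).fit(X[first_two], y[first_two])
        else:
            logger.warning("step 3 skipped: no type-1/2 training cases")
            self.model3_ = None
        return self

    def predict(self, X):
        X = _as_matrix(X)
        pred = self.model1_.predict(X).astype(int)
        merged = pred == APPROACH_MERGED
        if merged.any() and self.model2_ is not None:
            sub = self.model2_.predict(X[merged]).astype(int)
            out = np.where(sub == 3, 3, APPROACH_MERGED)
            pred[merged] = out
            still = merged.copy()
            still[merged] = out == APPROACH_MERGED
            if still.any() and self.model3_ is not None:
                pred[still] = self.model3_.predict(X[still]).astype(int)
            elif still.any():
                pred[still] = 1  # step-3 branch untrained; arbitrary but explicit
        elif merged.any():
            pred[merged] = 3  # step-2 branch untrained
        return pred


@dataclass(frozen=True)
class SeparationResult:
    """Per-step holdout accuracies, the composed confusion matrix, and the
    cumulative accuracy (trace/total of that matrix)."""

    step_accuracies: dict
    cumulative_accuracy: float
    confusion: object  # evaluate.ConfusionMatrix


def sequential_separation(
    X,
    y,
    learner: Optional[BaseEstimator] = None,
    reps: int = 500,
    test_fraction: float = 0.2,
    random_state: Optional[int] = None,
    cascade: bool = False,
) -> SeparationResult:
    """Evaluate the three-step scheme under the repeated-holdout protocol.

    Each step's accuracy is measured on its own subpopulation with the
    step-appropriate label coarsening; the cumulative accuracy is measured
    by fitting the full composed classifier on each training split and
    tabulating composed predictions on the test split across repetitions.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    ss = np.random.SeedSequence(random_state)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    step_accuracies: dict[str, Optional[float]] = {}
    y3 = np.where(y <= 3, APPROACH_MERGED, y)
    step_accuracies["step1_approach_vs_4_vs_5"] = repeated_holdout_accuracy(
        X, y3, learner, test_fraction, reps, seeds[0]
    )
    approach = y <= 3
    if approach.any() and len(np.unique(np.where(y[approach] <= 2, 0, 3))) == 2:
        step_accuracies["step2_12_vs_3"] = repeated_holdout_accuracy(
            X[approach], np.where(y[approach] <= 2, 0, 3), learner, test_fraction, reps, seeds[1]
        )
    else:
        logger.warning("step 2 accuracy skipped: approach subpopulation empty or single-class")
        step_accuracies["step2_12_vs_3"] = None
    first_two = y <= 2
    if first_two.any() and len(np.unique(y[first_two])) == 2:
        step_accuracies["step3_1_vs_2"] = repeated_holdout_accuracy(
            X[first_two], y[first_two], learner, test_fraction, reps, seeds[2]
        )
    else:
        logger.warning("step 3 accuracy skipped: type-1/2 subpopulation empty or single-class")
        step_accuracies["step3_1_vs_2"] = None

    rng = np.random.default_rng(seeds[3])
    n = len(y)
    n_test = max(1, int(round(n * test_fraction)))
    expert_all: list[int] = []
    pred_all: list[int] = []
    for rep in range(reps):
        for attempt in range(_MAX_RESAMPLE):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if len(np.unique(y[train_idx])) >= 2:
                break
            logger.warning("single-class training split resampled (rep %d)", rep)
        else:
            raise RuntimeError("could not draw a training split with two classes")
        model = SequentialSeparationClassifier(
            base_estimator=learner,
            cascade=cascade,
            random_state=int(rng.integers(2**31)),
        ).fit(X[train_idx], y[train_idx])
        expert_all.extend(y[test_idx].tolist())
        pred_all.extend(model.predict(X[test_idx]).tolist())

    confusion = build_confusion(expert_all, pred_all)
    cumulative = confusion.trace / confusion.total_classified
    return SeparationResult(step_accuracies, float(cumulative), confusion)
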