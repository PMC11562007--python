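"""Agreement metrics between algorithmic and expert type labels.

The central object is a 5x5 confusion matrix (expert type in rows,
algorithmic type in columns) with a separate column for unclassifiable
predictions.  Following the study convention, cases the algorithm leaves
unclassified -- like the descriptions the expert could not assign to any
type -- are excluded from accuracy denominators.  Internal arithmetic is
exact; rounding (half-up, matching how the accuracies are conventionally
printed) happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .core import TypeLabel

__all__ = [
    "ConfusionMatrix",
    "build_confusion",
    "overall_accuracy",
    "per_class_accuracy",
    "round_half_up",
    "summarize",
]

N_TYPES = 5


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 expert-by-predicted counts plus per-row unclassified predictions.

    ``counts[i, j]`` is the number of cases with expert type ``i+1`` and
    predicted type ``j+1``.  ``unclassified[i]`` counts expert-type-``i+1``
    cases the algorithm left unclassified.  ``expert_unclassified`` counts
    input cases excluded because the expert assigned no type.
    """

    counts: np.ndarray
    unclassified: np.ndarray = field(default_factory=lambda: np.zeros(N_TYPES, dtype=int))
    expert_unclassified: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        unclassified = np.asarray(self.unclassified, dtype=int)
        if counts.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"counts must be {N_TYPES}x{N_TYPES}, got {counts.shape}")
        if unclassified.shape != (N_TYPES,):
            raise ValueError(f"unclassified must have length {N_TYPES}")
        if (counts < 0).any() or (unclassified < 0).any() or self.expert_unclassified < 0:
            raise ValueError("confusion-matrix entries must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "unclassified", unclassified)

    @property
    def row_totals(self) -> np.ndarray:
        """Cases per expert type, including unclassified predictions."""
        return self.counts.sum(axis=1) + self.unclassified

    @property
    def total_cases(self) -> int:
        return int(self.counts.sum() + self.unclassified.sum() + self.expert_unclassified)

    @property
    def total_classified(self) -> int:
        """Cases with both an expert type and an algorithmic type."""
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))


def build_confusion(
    expert_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionMatrix:
    """Tabulate aligned expert and predicted label sequences.

    Label 0 (:data:`TypeLabel.UNCLASSIFIED`) on the predicted side goes to
    the unclassified column; on the expert side it excludes the case from
    the table (tracked in ``expert_unclassified``).
    """
    expert = [int(e) for e in expert_labels]
    predicted = [int(p) for p in predicted_labels]
    if len(expert) != len(predicted):
        raise ValueError(
            f"label sequences differ in length ({len(expert)} vs {len(predicted)})"
        )
    counts = np.zeros((N_TYPES, N_TYPES), dtype=int)
    unclassified = np.zeros(N_TYPES, dtype=int)
    expert_unclassified = 0
    for e, p in zip(expert, predicted):
        if not (0 <= e <= N_TYPES and 0 <= p <= N_TYPES):
            raise ValueError(f"labels must be in 0..{N_TYPES}, got expert={e}, predicted={p}")
        if e == 0:
            expert_unclassified += 1
        elif p == 0:
            unclassified[e - 1] += 1
        else:
            counts[e - 1, p - 1] += 1
    return ConfusionMatrix(counts, unclassified, expert_unclassified)


def overall_accuracy(m: ConfusionMatrix) -> float:
    """Percentage of classified cases on the diagonal (100 * trace / classified)."""
    if m.total_classified == 0:
        raise ValueError("overall accuracy undefined: no classified cases")
    return 100.0 * m.trace / m.total_classified


def per_class_accuracy(m: ConfusionMatrix) -> np.ndarray:
    """Percentage correctly defined per expert type; NaN for an empty type."""
    totals = m.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * np.diag(m.counts) / totals
    return np.where(totals > 0, out, np.nan)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding for reporting (2.25 -> 2.3 at 1 decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(m: ConfusionMatrix) -> dict:
    """Reporting-ready summary with conventional rounding (overall to 2
    decimals, per-class to 1)."""
    per_class = per_class_accuracy(m)
    return {
        "overall_accuracy_pct": round_half_up(overall_accuracy(m), 2),
        "per_class_accuracy_pct": [
            None if np.isnan(v) else round_half_up(v, 1) for v in per_class
        ],
        "row_totals": [int(v) for v in m.row_totals],
        "total_cases": m.total_cases,
        "total_classified": m.total_classified,
        "unclassified_predictions": int(m.unclassified.sum()),
        "expert_unclassified": int(m.expert_unclassified),
    }
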