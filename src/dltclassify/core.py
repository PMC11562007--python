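"""Domain model for the five-type classification of perceived difficult life tasks.

A respondent describes one current difficult life task (DLT) and rates it on
the "Types of Orientations in Difficult Situations" questionnaire (TODS).
Six of the eight TODS scales drive the classification: three *approach*
orientations (drive, thoroughness, opportunity) and three *avoidance*
orientations (rejection, inaction, insouciance), each a mean score on a
0-3 Likert-derived scale.  The free-text description is content-coded into a
sparse vector of category mention counts (the *markup*; the coding scheme has
187 categories, e.g. ``F6`` = threat to life/health, ``A1`` = positive intense
emotions, ``1B9`` = necessity).

An orientation is *expressed* when its score passes a per-scale threshold.
The default ("baseline") threshold is 1.5 inclusive -- the midpoint of the
0-3 range; the calibrated ("refined") preset raises thoroughness to a strict
1.65 and insouciance to a strict 1.85.

This module defines the data types (:class:`ScaleScores`,
:class:`MarkupVector`, :class:`Case`, :class:`ThresholdConfig`,
:class:`WeightedDictionary`, :class:`TypeLabel`), the expression predicate
:func:`is_expressed`, and :func:`expressed_sets` on which all decision rules
are built.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "APPROACH_SCALES",
    "AVOIDANCE_SCALES",
    "CLASSIFICATION_SCALES",
    "CARRIED_SCALES",
    "SCORE_MIN",
    "SCORE_MAX",
    "ConfigError",
    "TypeLabel",
    "ScaleScores",
    "MarkupVector",
    "Case",
    "ThresholdEntry",
    "ThresholdConfig",
    "WeightedDictionary",
    "default_registry",
    "is_expressed",
    "expressed_sets",
]

APPROACH_SCALES = ("drive", "thoroughness", "opportunity")
AVOIDANCE_SCALES = ("rejection", "inaction", "insouciance")
#: Canonical order of the six scales that enter the decision rules.
CLASSIFICATION_SCALES = APPROACH_SCALES + AVOIDANCE_SCALES
#: Scales carried in the data model but never consulted by any rule.
CARRIED_SCALES = ("threat_alert", "obstacle")

SCORE_MIN = 0.0
SCORE_MAX = 3.0


class ConfigError(ValueError):
    """Invalid threshold, dictionary, or registry configuration."""


class TypeLabel(enum.IntEnum):
    """The five perception types plus the reserved unclassifiable outcome.

    Types 1-3 are the approach subtypes, 4 mixes approach and avoidance,
    5 is pure avoidance.  ``UNCLASSIFIED`` (0) is reserved for profiles in
    which no orientation is expressed at all.
    """

    UNCLASSIFIED = 0
    DRIVEN = 1
    MAXIMAL = 2
    OPTIMAL = 3
    AMBIVALENT = 4
    EVASIVE = 5


def _check_score(value: float, name: str) -> float:
    value = float(value)
    if not (SCORE_MIN <= value <= SCORE_MAX):
        raise ValueError(
            f"scale score {name}={value!r} outside the admissible range "
            f"[{SCORE_MIN}, {SCORE_MAX}]"
        )
    return value


@dataclass(frozen=True)
class ScaleScores:
    """Per-respondent mean scores on the TODS scales (0-3 each).

    The six classification scales are mandatory; the threat-alert and
    obstacle scales may apply to both approach and avoidance, so they are
    carried for completeness but never consulted by the rules.
    """

    drive: float
    thoroughness: float
    opportunity: float
    rejection: float
    inaction: float
    insouciance: float
    threat_alert: Optional[float] = None
    obstacle: Optional[float] = None

    def __post_init__(self) -> None:
        for name in CLASSIFICATION_SCALES:
            object.__setattr__(self, name, _check_score(getattr(self, name), name))
        for name in CARRIED_SCALES:
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, _check_score(value, name))

    def __getitem__(self, scale: str) -> float:
        if scale not in CLASSIFICATION_SCALES + CARRIED_SCALES:
            raise KeyError(scale)
        return getattr(self, scale)


def default_registry() -> frozenset[str]:
    """The default set of admissible markup codes (187 entries).

    The published coding instruction is not available, so this registry is a
    synthetic stand-in: systematic ``<prefix><number>`` codes in the style of
    the published examples, guaranteed to contain the five codes the study
    names (A1, 1B9, C6, F6, 1D4).
    """

    prefixes = ("A", "B", "C", "D", "E", "F", "1A", "1B", "1C", "1D", "1E", "1F")
    codes = [f"{p}{i}" for p in prefixes for i in range(1, 17)]
    return frozenset(codes[:187])


DEFAULT_REGISTRY = default_registry()


@dataclass(frozen=True)
class MarkupVector:
    """Sparse nonnegative mention counts of content-analysis categories.

    ``counts`` maps category codes to positive integer counts; absent code
    means count zero.  Every key must belong to ``registry``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    registry: frozenset[str] = DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for code, count in dict(self.counts).items():
            if code not in self.registry:
                raise ConfigError(f"markup code {code!r} not in the registry")
            n = int(count)
            if n != count or n < 0:
                raise ValueError(f"markup count for {code!r} must be a nonnegative integer, got {count!r}")
            if n:
                clean[code] = n
        object.__setattr__(self, "counts", clean)

    def get(self, code: str) -> int:
        """Count for ``code`` (0 when absent); unknown codes are a config error."""
        if code not in self.registry:
            raise ConfigError(f"markup code {code!r} not in the registry")
        return self.counts.get(code, 0)

    __getitem__ = get

    def __iter__(self):
        return iter(self.counts)


@dataclass(frozen=True)
class Case:
    """One respondent: scale profile + markup + optional expert type label."""

    case_id: str
    scales: ScaleScores
    markup: MarkupVector = field(default_factory=MarkupVector)
    expert_label: Optional[TypeLabel] = None

    def __post_init__(self) -> None:
        if self.expert_label is not None:
            object.__setattr__(self, "expert_label", TypeLabel(self.expert_label))


@dataclass(frozen=True)
class ThresholdEntry:
    """An expression threshold with its comparison convention.

    ``inclusive`` means the score passes at exactly the threshold
    ("1.5 and higher"); strict means it must exceed it ("greater than 1.65").
    """

    threshold: float
    inclusive: bool = True

    def __post_init__(self) -> None:
        t = float(self.threshold)
        if not (SCORE_MIN <= t <= SCORE_MAX):
            raise ConfigError(f"threshold {t!r} outside [{SCORE_MIN}, {SCORE_MAX}]")
        object.__setattr__(self, "threshold", t)
        object.__setattr__(self, "inclusive", bool(self.inclusive))


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-scale expression thresholds for the six classification scales."""

    entries: Mapping[str, ThresholdEntry]

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        missing = set(CLASSIFICATION_SCALES) - set(entries)
        extra = set(entries) - set(CLASSIFICATION_SCALES)
        if missing or extra:
            raise ConfigError(
                f"threshold config must cover exactly the six classification scales; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for scale, entry in entries.items():
            if not isinstance(entry, ThresholdEntry):
                entries[scale] = ThresholdEntry(*entry) if isinstance(entry, (tuple, list)) else ThresholdEntry(**entry)
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, scale: str) -> ThresholdEntry:
        return self.entries[scale]

    def items(self):
        return ((s, self.entries[s]) for s in CLASSIFICATION_SCALES)

    def replace(self, **overrides: ThresholdEntry) -> "ThresholdConfig":
        entries = dict(self.entries)
        entries.update(overrides)
        return ThresholdConfig(entries)

    @classmethod
    def baseline(cls) -> "ThresholdConfig":
        """All six scales at 1.5, inclusive (the scale midpoint convention)."""
        return cls({s: ThresholdEntry(1.5, True) for s in CLASSIFICATION_SCALES})

    @classmethod
    def refined(cls) -> "ThresholdConfig":
        """Calibrated preset: thoroughness > 1.65 and insouciance > 1.85 (strict),
        the other four at 1.5 inclusive."""
        cfg = cls.baseline()
        return cfg.replace(
            thoroughness=ThresholdEntry(1.65, False),
            insouciance=ThresholdEntry(1.85, False),
        )

    @classmethod
    def from_preset(cls, name: str) -> "ThresholdConfig":
        try:
            return {"baseline": cls.baseline, "refined": cls.refined}[name]()
        except KeyError:
            raise ConfigError(f"unknown threshold preset {name!r}; use 'baseline' or 'refined'") from None


@dataclass(frozen=True)
class WeightedDictionary:
    """A weighted list of markup subcategories characterizing one type.

    Weights run from 1 (least significant) to 3 (most significant).  The
    weighted sum of a case's markup counts over the dictionary's codes is the
    evidence score used to separate the driven from the maximal type.
    """

    name: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        entries = tuple((str(c), int(w)) for c, w in self.entries)
        if not entries:
            raise ConfigError(f"dictionary {self.name!r} must be nonempty")
        codes = [c for c, _ in entries]
        if len(set(codes)) != len(codes):
            raise ConfigError(f"dictionary {self.name!r} has duplicate codes")
        for code, weight in entries:
            if weight not in (1, 2, 3):
                raise ConfigError(
                    f"dictionary {self.name!r}: weight for {code!r} must be in {{1,2,3}}, got {weight}"
                )
        object.__setattr__(self, "entries", entries)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.entries)

    def weighted_sum(self, markup: MarkupVector) -> int:
        """S = sum over (code, w) of w * count(code)."""
        return sum(w * markup.get(c) for c, w in self.entries)


def check_disjoint(dict1: WeightedDictionary, dict2: WeightedDictionary) -> None:
    overlap = dict1.codes & dict2.codes
    if overlap:
        raise ConfigError(
            f"dictionaries {dict1.name!r} and {dict2.name!r} overlap on {sorted(overlap)}"
        )


def is_expressed(score: float, entry: ThresholdEntry) -> bool:
    """Whether a scale score passes its expression threshold.

    Inclusive entries use ``score >= threshold``; strict entries use
    ``score > threshold``.
    """
    score = float(score)
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score!r} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if entry.inclusive:
        return score >= entry.threshold
    return score > entry.threshold


def expressed_sets(
    scales: ScaleScores, config: ThresholdConfig
) -> tuple[frozenset[str], frozenset[str]]:
    """The expressed approach scales and expressed avoidance scales of a profile."""
    approach = frozenset(
        s for s in APPROACH_SCALES if is_expressed(scales[s], config[s])
    )
    avoidance = frozenset(
        s for s in AVOIDANCE_SCALES if is_expressed(scales[s], config[s])
    )
    return approach, avoidance
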