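"""Generator of labeled synthetic cases with the statistical structure of
the five perception types.

The study's 600-respondent dataset is not deposited, so every other module
is exercised on synthetic cases that emulate the qualitative structure of
the types:

* type 1 (driven): drive highest among expressed approach scales, no
  avoidance expressed; markup rich in positive-intense-emotion codes (A1);
* type 2 (maximal): thoroughness strongly expressed, no avoidance; markup
  rich in necessity/maximum-result codes (1B9, C6);
* type 3 (optimal): opportunity carries the highest approach score; planful
  coping (1D4) frequent;
* type 4 (ambivalent): at least one approach and one avoidance orientation
  expressed;
* type 5 (evasive): avoidance expressed, no approach scale passing its
  threshold.

Scale scores are drawn from per-type normal distributions truncated to
[0, 3]; markup counts are Poisson with per-type rates; the
extreme-situation category (F6) is emitted with a per-type probability and
is always zero for types 1 and 2, whose situations are by definition not
extreme.  The published per-type descriptive statistics are unavailable, so
the default means/sds are the package's own choices consistent with the
qualitative definitions; no distributional fidelity to the study sample is
claimed.

With ``enforce_region`` on (the default, "noise-free" mode), rejection
sampling guarantees each case is classified back to its generating label by
the rule engine under the active thresholds and dictionaries, with a
configurable margin on the dictionary-sum difference for types 1/2.  The
default mixture reproduces the study's per-type counts
(67, 89, 139, 245, 60; total 600).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .core import (
    CARRIED_SCALES,
    CLASSIFICATION_SCALES,
    Case,
    MarkupVector,
    ScaleScores,
    ThresholdConfig,
    TypeLabel,
    WeightedDictionary,
    default_registry,
)
from .rules import DEFAULT_EXTREME_CODE, classify_case, default_dictionaries

__all__ = ["ScaleDist", "TypeGenConfig", "generate_case", "generate_dataset"]

#: Study per-type case counts (total 600).
DEFAULT_MIXTURE = {1: 67, 2: 89, 3: 139, 4: 245, 5: 60}

_TYPE_SCALE_MEANS = {
    1: dict(drive=2.5, thoroughness=2.0, opportunity=1.8,
            rejection=0.8, inaction=0.7, insouciance=0.9,
            threat_alert=1.9, obstacle=1.6),
    2: dict(drive=2.0, thoroughness=2.6, opportunity=1.8,
            rejection=0.8, inaction=0.8, insouciance=0.9,
            threat_alert=2.0, obstacle=1.7),
    3: dict(drive=1.9, thoroughness=1.5, opportunity=2.5,
            rejection=0.9, inaction=0.8, insouciance=1.0,
            threat_alert=1.83, obstacle=1.53),
    4: dict(drive=2.0, thoroughness=1.9, opportunity=1.9,
            rejection=2.1, inaction=1.9, insouciance=1.7,
            threat_alert=2.1, obstacle=1.85),
    5: dict(drive=0.9, thoroughness=0.8, opportunity=1.0,
            rejection=2.3, inaction=2.0, insouciance=2.0,
            threat_alert=2.21, obstacle=1.89),
}

# Poisson mention rates for the markup codes each type's descriptions favor.
_TYPE_MARKUP_RATES = {
    1: {"A1": 2.0, "A2": 1.0, "B3": 0.8, "C2": 0.8, "1D4": 1.2, "1B9": 0.1, "C6": 0.1},
    2: {"1B9": 2.0, "C6": 1.8, "B7": 1.0, "C8": 1.0, "1D4": 1.0, "A1": 0.1},
    3: {"1D4": 1.5, "A1": 0.3, "B3": 0.3, "D1": 0.2},
    4: {"1D4": 0.4, "E4": 0.5, "D5": 0.5},
    5: {"E6": 0.5, "D5": 0.6},
}

_TYPE_EXTREME_PROB = {1: 0.0, 2: 0.0, 3: 0.15, 4: 0.2, 5: 0.3}


@dataclass(frozen=True)
class ScaleDist:
    """Normal(mean, sd) truncated to the score range [0, 3]."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class TypeGenConfig:
    """Per-type generative parameters.

    ``margin`` is the minimum dictionary-sum separation |S1 - S2| required
    of types 1 and 2 in region-enforced mode, keeping the driven/maximal
    split off its tie boundary.
    """

    scale_dists: Mapping[int, Mapping[str, ScaleDist]]
    markup_rates: Mapping[int, Mapping[str, float]]
    extreme_prob: Mapping[int, float]
    mixture: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    enforce_region: bool = True
    margin: float = 1.0
    max_rejects: int = 1000
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig.refined)
    dictionaries: tuple[WeightedDictionary, WeightedDictionary] = field(
        default_factory=default_dictionaries
    )
    extreme_code: str = DEFAULT_EXTREME_CODE
    registry: frozenset = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        for label, p in self.extreme_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"extreme probability for type {label} outside [0,1]")
        for label, rates in self.markup_rates.items():
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"negative markup rate for type {label}")
        if any(n < 0 for n in self.mixture.values()):
            raise ValueError("mixture counts must be nonnegative")

    @classmethod
    def default(
        cls,
        sd: float = 0.35,
        enforce_region: bool = True,
        mixture: Optional[Mapping[int, int]] = None,
        **overrides,
    ) -> "TypeGenConfig":
        """Default configuration; ``sd`` sets one common scale-score spread."""
        dists = {
            label: {name: ScaleDist(mean, sd) for name, mean in means.items()}
            for label, means in _TYPE_SCALE_MEANS.items()
        }
        return cls(
            scale_dists=dists,
            markup_rates={k: dict(v) for k, v in _TYPE_MARKUP_RATES.items()},
            extreme_prob=dict(_TYPE_EXTREME_PROB),
            mixture=dict(mixture) if mixture is not None else dict(DEFAULT_MIXTURE),
            enforce_region=enforce_region,
            **overrides,
        )


def _truncated_normal(dist: ScaleDist, rng: np.random.Generator) -> float:
    for _ in range(1000):
        x = rng.normal(dist.mean, dist.sd)
        if 0.0 <= x <= 3.0:
            return float(x)
    # sd enormous relative to the window; fall back to clipping
    return float(np.clip(rng.normal(dist.mean, dist.sd), 0.0, 3.0))


def _sample_once(label: int, cfg: TypeGenConfig, rng: np.random.Generator, case_id: str) -> Case:
    dists = cfg.scale_dists[label]
    values = {name: _truncated_normal(d, rng) for name, d in dists.items()}
    scales = ScaleScores(
        **{s: values[s] for s in CLASSIFICATION_SCALES},
        **{s: values.get(s) for s in CARRIED_SCALES},
    )
    counts = {}
    for code, rate in cfg.markup_rates[label].items():
        n = int(rng.poisson(rate))
        if n:
            counts[code] = n
    if label in (1, 2):
        counts.pop(cfg.extreme_code, None)  # extreme situations never occur for types 1/2
    elif rng.random() < cfg.extreme_prob.get(label, 0.0):
        counts[cfg.extreme_code] = 1 + int(rng.poisson(0.5))
    else:
        counts.pop(cfg.extreme_code, None)
    markup = MarkupVector(counts, cfg.registry)
    return Case(case_id, scales, markup, TypeLabel(label))


def _in_region(case: Case, label: int, cfg: TypeGenConfig) -> bool:
    if classify_case(case, cfg.thresholds, cfg.dictionaries, cfg.extreme_code) != label:
        return False
    if label in (1, 2) and cfg.margin > 0:
        d1, d2 = cfg.dictionaries
        diff = d1.weighted_sum(case.markup) - d2.weighted_sum(case.markup)
        if label == 1 and diff < cfg.margin:
            return False
        if label == 2 and -diff < cfg.margin:
            return False
    return True


def generate_case(
    label: int,
    cfg: Optional[TypeGenConfig] = None,
    rng: Optional[np.random.Generator] = None,
    case_id: str = "S0001",
) -> Case:
    """Draw one case of the given type (1-5).

    In region-enforced mode the draw is rejection-sampled until the rule
    engine classifies it back to ``label``; an infeasible configuration
    fails loudly after ``max_rejects`` attempts.
    """
    label = int(TypeLabel(label))
    if label not in (1, 2, 3, 4, 5):
        raise ValueError(f"label must be a type 1-5, got {label}")
    cfg = cfg if cfg is not None else TypeGenConfig.default()
    rng = rng if rng is not None else np.random.default_rng()
    if not cfg.enforce_region:
        return _sample_once(label, cfg, rng, case_id)
    for _ in range(cfg.max_rejects):
        case = _sample_once(label, cfg, rng, case_id)
        if _in_region(case, label, cfg):
            return case
    raise RuntimeError(
        f"could not sample a case of type {label} inside its rule region after "
        f"{cfg.max_rejects} attempts; the generative parameters are incompatible "
        "with the active thresholds/dictionaries"
    )


def generate_dataset(
    cfg: Optional[TypeGenConfig] = None,
    seed: Optional[int] = None,
) -> list[Case]:
    """Draw a labeled dataset matching the mixture exactly, in shuffled order."""
    cfg = cfg if cfg is not None else TypeGenConfig.default()
    total = sum(cfg.mixture.values())
    if total < 1:
        raise ValueError("mixture is empty: no cases requested")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(total)))
    cases: list[Case] = []
    i = 0
    for label in sorted(cfg.mixture):
        for _ in range(cfg.mixture[label]):
            i += 1
            cases.append(generate_case(label, cfg, rng, case_id=f"S{i:0{width}d}"))
    order = rng.permutation(len(cases))
    return [cases[j] for j in order]
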