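"""Reading and writing case tables and configuration files.

Case tables are CSV (or TSV, by file extension) with one row per
respondent.  Canonical columns:

``case_id``
    unique string identifier;
``drive, thoroughness, opportunity, rejection, inaction, insouciance``
    the six classification scale scores in [0, 3] (mandatory);
``threat_alert, obstacle``
    the two carried scales (optional);
``m_<code>``
    markup mention counts, one column per category code (absent column =
    count 0);
``expert_label``
    optional expert type, 1-5 or 0/"UNCLASSIFIED" (empty = no label).

Threshold and dictionary configurations are YAML; see
:func:`save_thresholds` / :func:`save_dictionaries` for the schema.  Both
round-trip losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    CARRIED_SCALES,
    CLASSIFICATION_SCALES,
    Case,
    ConfigError,
    MarkupVector,
    ScaleScores,
    ThresholdConfig,
    ThresholdEntry,
    TypeLabel,
    WeightedDictionary,
    check_disjoint,
    default_registry,
)

__all__ = [
    "read_cases",
    "write_cases",
    "frame_to_cases",
    "cases_to_frame",
    "feature_matrix",
    "expert_labels",
    "load_thresholds",
    "save_thresholds",
    "load_dictionaries",
    "save_dictionaries",
    "load_configs",
]

logger = logging.getLogger(__name__)

MARKUP_PREFIX = "m_"


def _sep_for(path: Union[str, Path]) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _parse_label(value) -> Optional[TypeLabel]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, str):
        v = value.strip().upper()
        if v in ("UNCLASSIFIED", "UNC"):
            return TypeLabel.UNCLASSIFIED
        value = v
    try:
        return TypeLabel(int(float(value)))
    except (ValueError, KeyError):
        raise ValueError(f"cannot parse expert label {value!r}") from None


def frame_to_cases(
    df: pd.DataFrame,
    registry: Optional[frozenset] = None,
    on_unknown: str = "error",
) -> list[Case]:
    """Convert a canonical-schema DataFrame into Case objects.

    Unknown markup columns are a fatal error by default; ``on_unknown='drop'``
    discards them with a logged warning.
    """
    registry = registry if registry is not None else default_registry()
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    missing = [s for s in CLASSIFICATION_SCALES if s not in df.columns]
    if missing:
        raise ValueError(f"case table is missing scale column(s): {missing}")

    markup_cols = [c for c in df.columns if c.startswith(MARKUP_PREFIX)]
    unknown = [c for c in markup_cols if c[len(MARKUP_PREFIX):] not in registry]
    if unknown:
        if on_unknown == "error":
            raise ConfigError(f"unknown markup code column(s): {unknown}")
        logger.warning("dropping unknown markup columns: %s", unknown)
        markup_cols = [c for c in markup_cols if c not in unknown]

    has_ids = "case_id" in df.columns
    width = max(4, len(str(len(df))))
    cases: list[Case] = []
    seen_ids: set[str] = set()
    for pos, (_, row) in enumerate(df.iterrows()):
        rownum = pos + 1
        case_id = str(row["case_id"]) if has_ids else f"R{rownum:0{width}d}"
        if case_id in seen_ids:
            raise ValueError(f"duplicate case_id {case_id!r} at row {rownum}")
        seen_ids.add(case_id)

        scale_values = {}
        for scale in CLASSIFICATION_SCALES + CARRIED_SCALES:
            if scale not in df.columns:
                continue
            raw = row[scale]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                if scale in CLASSIFICATION_SCALES:
                    raise ValueError(f"row {rownum}, column {scale!r}: missing score")
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {rownum}, column {scale!r}: non-numeric score {raw!r}"
                ) from None
            scale_values[scale] = value
        try:
            scales = ScaleScores(**scale_values)
        except ValueError as exc:
            raise ValueError(f"row {rownum} ({case_id}): {exc}") from None

        counts = {}
        for col in markup_cols:
            raw = row[col]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            n = int(raw)
            if n:
                counts[col[len(MARKUP_PREFIX):]] = n
        try:
            markup = MarkupVector(counts, registry)
        except ValueError as exc:
            raise ValueError(f"row {rownum} ({case_id}): {exc}") from None

        label = _parse_label(row["expert_label"]) if "expert_label" in df.columns else None
        cases.append(Case(case_id, scales, markup, label))
    return cases


def read_cases(
    path: Union[str, Path],
    registry: Optional[frozenset] = None,
    on_unknown: str = "error",
) -> list[Case]:
    """Read a CSV/TSV case table (see module docstring for the schema)."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return frame_to_cases(df, registry=registry, on_unknown=on_unknown)


def cases_to_frame(cases: Sequence[Case]) -> pd.DataFrame:
    """Canonical-schema DataFrame for a list of cases.

    Markup columns cover the union of codes with a nonzero count; the
    carried scales appear only if some case has them.
    """
    codes = sorted({code for c in cases for code in c.markup.counts})
    carried = [s for s in CARRIED_SCALES if any(c.scales[s] is not None for c in cases)]
    rows = []
    for c in cases:
        row: dict = {"case_id": c.case_id}
        for scale in CLASSIFICATION_SCALES:
            row[scale] = c.scales[scale]
        for scale in carried:
            row[scale] = c.scales[scale]
        for code in codes:
            row[MARKUP_PREFIX + code] = c.markup.get(code)
        row["expert_label"] = int(c.expert_label) if c.expert_label is not None else None
        rows.append(row)
    return pd.DataFrame(rows)


def write_cases(cases: Sequence[Case], path: Union[str, Path], header: Optional[str] = None) -> None:
    """Write cases as CSV/TSV; ``header`` becomes leading ``#`` comment lines."""
    df = cases_to_frame(cases)
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def feature_matrix(cases: Sequence[Case], features: Sequence[str]) -> pd.DataFrame:
    """DataFrame of named features: scale names and/or ``m_<code>`` columns."""
    rows = []
    for c in cases:
        row = {}
        for f in features:
            if f.startswith(MARKUP_PREFIX):
                row[f] = c.markup.get(f[len(MARKUP_PREFIX):])
            else:
                value = c.scales[f]
                if value is None:
                    raise ValueError(f"case {c.case_id}: carried scale {f!r} not present")
                row[f] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=list(features))


def expert_labels(cases: Sequence[Case], require: bool = True) -> np.ndarray:
    """Expert labels as an int array (0 = unclassified)."""
    if require and any(c.expert_label is None for c in cases):
        raise ValueError("labels required: some cases carry no expert label")
    return np.array(
        [int(c.expert_label) if c.expert_label is not None else 0 for c in cases],
        dtype=int,
    )


def save_thresholds(config: ThresholdConfig, path: Union[str, Path]) -> None:
    data = {
        "thresholds": {
            scale: {"threshold": entry.threshold, "inclusive": entry.inclusive}
            for scale, entry in config.items()
        }
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_thresholds(path: Union[str, Path]) -> ThresholdConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "thresholds" not in data:
        raise ConfigError(f"{path}: expected a top-level 'thresholds' mapping")
    entries = {}
    for scale, spec in data["thresholds"].items():
        entries[scale] = ThresholdEntry(
            threshold=spec["threshold"], inclusive=spec.get("inclusive", True)
        )
    return ThresholdConfig(entries)


def save_dictionaries(
    dict1: WeightedDictionary, dict2: WeightedDictionary, path: Union[str, Path]
) -> None:
    data = {
        "dictionary1": {"name": dict1.name, "entries": {c: w for c, w in dict1.entries}},
        "dictionary2": {"name": dict2.name, "entries": {c: w for c, w in dict2.entries}},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_dictionaries(path: Union[str, Path]) -> tuple[WeightedDictionary, WeightedDictionary]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "dictionary1" not in data or "dictionary2" not in data:
        raise ConfigError(f"{path}: expected top-level 'dictionary1' and 'dictionary2'")
    dicts = []
    for key in ("dictionary1", "dictionary2"):
        spec = data[key]
        dicts.append(
            WeightedDictionary(
                spec.get("name", key), tuple(spec["entries"].items())
            )
        )
    check_disjoint(*dicts)
    return dicts[0], dicts[1]


def load_configs(
    threshold_path: Optional[Union[str, Path]] = None,
    dict_path: Optional[Union[str, Path]] = None,
    preset: str = "refined",
) -> tuple[ThresholdConfig, WeightedDictionary, WeightedDictionary]:
    """Resolve thresholds and dictionaries from files, falling back to the
    named preset and the packaged example dictionaries."""
    from .rules import default_dictionaries

    thresholds = (
        load_thresholds(threshold_path)
        if threshold_path is not None
        else ThresholdConfig.from_preset(preset)
    )
    dict1, dict2 = (
        load_dictionaries(dict_path) if dict_path is not None else default_dictionaries()
    )
    return thresholds, dict1, dict2
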