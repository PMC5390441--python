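"""Profiling of dataset columns into the metadata features that allocation rules test.

Each column of a cohort dataset is summarized into a :class:`VariableMetadata`
record: name, optional human-readable label, inferred type (number / date /
string), scale level (ratio / ordinal / nominal / dichotomous), the number of
distinct values, the proportion of the most frequent value, and — for numeric
columns — the median and interquartile range. These features are the only
information the rule engine sees; raw participant values never leave this
module.

Cohort exports are messy, so parsing is deliberately permissive: a column is
numeric (or date) if at least a configurable fraction of its non-missing cells
parse as such, and a configurable token list defines missingness.
"""

from __future__ import annotations

import enum
import logging
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("harmonizer")

__all__ = [
    "Dtype",
    "Scale",
    "ProfileConfig",
    "VariableMetadata",
    "infer_dtype",
    "infer_scale",
    "profile_variable",
    "profile_dataset",
    "read_dataset",
    "read_labels",
    "profiles_to_frame",
    "frame_to_profiles",
]


class Dtype(str, enum.Enum):
    """Inferred storage type of a source variable."""

    NUMBER = "number"
    DATE = "date"
    STRING = "string"


class Scale(str, enum.Enum):
    """Measurement scale level of a source variable."""

    RATIO = "ratio"
    ORDINAL = "ordinal"
    NOMINAL = "nominal"
    DICHOTOMOUS = "dichotomous"


#: Default cell contents treated as missing (compared case-insensitively, stripped).
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", ".", "NULL")

#: Default date patterns, ISO first. A column that parses as numeric is never
#: re-classified as date, so purely numeric formats like 20010304 are excluded.
DEFAULT_DATE_PATTERNS = ("%Y-%m-%d", "%Y/%m/%d", "%d.%m.%Y", "%m/%d/%Y", "%d/%m/%Y")


@dataclass(frozen=True)
class ProfileConfig:
    """Tunable parsing thresholds for column profiling.

    Parameters
    ----------
    missing_tokens:
        Cell values (case-insensitive, whitespace-stripped) treated as missing.
    numeric_threshold, date_threshold:
        Minimum fraction of non-missing cells that must parse for a column to
        be typed number resp. date. Number takes precedence over date.
    k_scale:
        Numeric columns with more than ``k_scale`` distinct values are ratio
        scaled; integer-coded columns with 3..k_scale levels are ordinal.
    date_patterns:
        ``strptime`` patterns tried in order.
    """

    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    numeric_threshold: float = 0.95
    date_threshold: float = 0.95
    k_scale: int = 10
    date_patterns: tuple[str, ...] = DEFAULT_DATE_PATTERNS

    def __post_init__(self) -> None:
        if not 0 < self.numeric_threshold <= 1 or not 0 < self.date_threshold <= 1:
            raise ValueError("parse thresholds must lie in (0, 1]")
        if self.k_scale < 2:
            raise ValueError("k_scale must be at least 2")

    def is_missing(self, cell: object) -> bool:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return True
        text = str(cell).strip()
        lowered = {t.lower() for t in self.missing_tokens}
        return text.lower() in lowered


@dataclass
class VariableMetadata:
    """Feature profile of one source variable; the unit the rules operate on.

    ``median`` and ``iqr`` are populated only for numeric columns with at
    least one parseable value. ``prop_most_frequent`` is the modal count
    divided by ``n_nonmissing`` (0.0 for an empty column).
    """

    name: str
    label: Optional[str]
    dtype: Dtype
    scale: Scale
    n_values: int
    prop_most_frequent: float
    median: Optional[float]
    iqr: Optional[float]
    n_nonmissing: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_most_frequent <= 1.0:
            raise ValueError("prop_most_frequent must lie in [0, 1]")
        if self.iqr is not None and self.iqr < 0:
            raise ValueError("iqr must be non-negative")
        if self.scale is Scale.DICHOTOMOUS and self.n_values > 2:
            raise ValueError("dichotomous scale implies at most 2 distinct values")

    def feature(self, name: str) -> Optional[float]:
        """Numeric feature lookup used by threshold rules; None when absent."""
        if name in ("median", "iqr"):
            return getattr(self, name)
        if name == "n_values":
            return float(self.n_values)
        if name == "prop_most_frequent":
            return float(self.prop_most_frequent)
        raise KeyError(f"unknown metadata feature {name!r}")


def _parse_number(text: str) -> Optional[float]:
    try:
        value = float(text.replace(",", ".")) if "," in text else float(text)
    except ValueError:
        return None
    return value if np.isfinite(value) else None


def _parse_date(text: str, patterns: Sequence[str]) -> bool:
    for pattern in patterns:
        try:
            datetime.strptime(text.strip(), pattern)
            return True
        except ValueError:
            continue
    return False


def infer_dtype(values: Iterable[object], config: ProfileConfig | None = None) -> Dtype:
    """Infer number / date / string from raw cell texts.

    A column is ``number`` if at least ``numeric_threshold`` of its non-missing
    cells parse as numerals, ``date`` if at least ``date_threshold`` parse
    under the configured patterns; number takes precedence when both hold.
    All-missing columns fall back to ``string`` with a warning.
    """
    config = config or ProfileConfig()
    cells = [str(v).strip() for v in values if not config.is_missing(v)]
    if not cells:
        logger.warning("all-missing column: dtype defaults to string")
        return Dtype.STRING
    n = len(cells)
    n_numeric = sum(_parse_number(c) is not None for c in cells)
    if n_numeric / n >= config.numeric_threshold:
        return Dtype.NUMBER
    n_date = sum(_parse_date(c, config.date_patterns) for c in cells)
    if n_date / n >= config.date_threshold:
        return Dtype.DATE
    return Dtype.STRING


def infer_scale(
    values: Sequence[object],
    dtype: Dtype,
    config: ProfileConfig | None = None,
) -> Scale:
    """Infer the scale level from parsed non-missing values.

    Decision rule: dichotomous when there are at most two distinct values;
    numeric columns with more than ``k_scale`` distinct values are ratio;
    integer-coded numeric columns with 3..k_scale levels are ordinal (numeric
    non-integer few-level columns stay ratio — a measured quantity does not
    become categorical by having few observed values); everything else is
    nominal.
    """
    config = config or ProfileConfig()
    distinct = set(values)
    if not distinct:
        logger.warning("empty column: scale defaults to nominal")
        return Scale.NOMINAL
    if len(distinct) <= 2:
        return Scale.DICHOTOMOUS
    if dtype is Dtype.NUMBER:
        if len(distinct) > config.k_scale:
            return Scale.RATIO
        if all(float(v) == int(float(v)) for v in distinct):
            return Scale.ORDINAL
        return Scale.RATIO
    return Scale.NOMINAL


def profile_variable(
    name: str,
    label: Optional[str],
    values: Iterable[object],
    config: ProfileConfig | None = None,
) -> VariableMetadata:
    """Profile a single column into a :class:`VariableMetadata` record.

    For numeric columns, cells that fail to parse as numerals (at most 5%
    under the default threshold) carry no usable value and are treated as
    missing, so distinct-value counts, modal proportion, median and IQR are
    all computed over the parsed values. Quantiles use linear interpolation
    between order statistics (numpy's default, "type 7").
    """
    config = config or ProfileConfig()
    raw = [str(v).strip() for v in values if not config.is_missing(v)]
    dtype = infer_dtype(raw, config)

    if dtype is Dtype.NUMBER:
        parsed: list[object] = [x for c in raw if (x := _parse_number(c)) is not None]
    else:
        parsed = list(raw)

    n_nonmissing = len(parsed)
    if n_nonmissing:
        counts = pd.Series(parsed).value_counts()
        n_values = int(counts.size)
        prop_most_frequent = float(counts.iloc[0]) / n_nonmissing
    else:
        n_values = 0
        prop_most_frequent = 0.0

    median: Optional[float] = None
    iqr: Optional[float] = None
    if dtype is Dtype.NUMBER and n_nonmissing:
        arr = np.asarray(parsed, dtype=float)
        median = float(np.median(arr))
        q1, q3 = np.percentile(arr, [25.0, 75.0])
        iqr = float(q3 - q1)

    scale = infer_scale(parsed, dtype, config)
    return VariableMetadata(
        name=name,
        label=label,
        dtype=dtype,
        scale=scale,
        n_values=n_values,
        prop_most_frequent=prop_most_frequent,
        median=median,
        iqr=iqr,
        n_nonmissing=n_nonmissing,
    )


def profile_dataset(
    table: Union[pd.DataFrame, str, Path],
    labels: Optional[Mapping[str, str]] = None,
    config: ProfileConfig | None = None,
) -> list[VariableMetadata]:
    """Profile every column of a dataset, in column order.

    ``table`` may be a DataFrame or a CSV path. Duplicate column names are a
    hard error (allocation is keyed by variable name within a dataset).
    Labels missing from the sidecar leave ``label`` absent.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_dataset(table)
    names = list(table.columns)
    duplicates = sorted({n for n in names if names.count(n) > 1})
    if duplicates:
        raise ValueError(f"duplicate column names: {', '.join(duplicates)}")
    labels = labels or {}
    return [
        profile_variable(name, labels.get(name), table[name].tolist(), config)
        for name in names
    ]


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV with all cells kept as text (missingness is handled here)."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_labels(path: Union[str, Path]) -> dict[str, str]:
    """Read a ``name,label`` sidecar CSV into a mapping."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"name", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(f"label sidecar must have columns {sorted(required)}")
    return dict(zip(frame["name"], frame["label"]))


_PROFILE_COLUMNS = [
    "name",
    "label",
    "dtype",
    "scale",
    "n_values",
    "prop_most_frequent",
    "median",
    "iqr",
    "n_nonmissing",
]


def profiles_to_frame(profiles: Sequence[VariableMetadata]) -> pd.DataFrame:
    """Serialize profiles to a DataFrame (one record per variable)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "name": p.name,
                "label": p.label if p.label is not None else "",
                "dtype": p.dtype.value,
                "scale": p.scale.value,
                "n_values": p.n_values,
                "prop_most_frequent": p.prop_most_frequent,
                "median": p.median,
                "iqr": p.iqr,
                "n_nonmissing": p.n_nonmissing,
            }
        )
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)


def frame_to_profiles(frame: pd.DataFrame) -> list[VariableMetadata]:
    """Inverse of :func:`profiles_to_frame`."""
    profiles = []
    for _, row in frame.iterrows():
        label = row.get("label")
        if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
            label = None
        median = row.get("median")
        iqr = row.get("iqr")
        median = None if median is None or pd.isna(median) else float(median)
        iqr = None if iqr is None or pd.isna(iqr) else float(iqr)
        profiles.append(
            VariableMetadata(
                name=str(row["name"]),
                label=label,
                dtype=Dtype(row["dtype"]),
                scale=Scale(row["scale"]),
                n_values=int(row["n_values"]),
                prop_most_frequent=float(row["prop_most_frequent"]),
                median=median,
                iqr=iqr,
                n_nonmissing=int(row["n_nonmissing"]),
            )
        )
    return profiles


def normalize_text(text: str) -> str:
    """Case- and accent-insensitive normalization used for substring rules."""
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return stripped.casefold()
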