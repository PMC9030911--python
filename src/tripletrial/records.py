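"""Participant-level trial records and delimited-text I/O.

One record per motorcycle-taxi driver: baseline covariates, baseline
helmet-use consistency (the stratification variable), assigned study arm,
and binary helmet-use outcomes at the week-3 and week-6 survey waves.
Missing values are explicit ``None`` in memory and empty cells on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISTRICTS = ("D1", "D2", "D3")
EDUCATION_LEVELS = ("elementary_or_none", "junior_high_or_above")
DRIVING_SETTINGS = ("urban", "suburban", "both")
FREQ_LEVELS = ("never", "sometimes", "usually", "always")
ARMS = ("control", "fear", "social")
STRATA = ("consistent", "inconsistent")

#: CSV column order; also the authoritative schema.
COLUMNS = (
    "id", "district", "age", "education", "married", "has_children",
    "phone_self_owned", "household_size", "driving_setting", "night_freq",
    "speeding_freq", "weekend_freq", "baseline_consistent", "arm",
    "outcome_wk3", "outcome_wk6",
)

_CATEGORICAL_LEVELS = {
    "district": DISTRICTS,
    "education": EDUCATION_LEVELS,
    "driving_setting": DRIVING_SETTINGS,
    "night_freq": FREQ_LEVELS,
    "speeding_freq": FREQ_LEVELS,
    "weekend_freq": FREQ_LEVELS,
    "arm": ARMS,
}
_BINARY_FIELDS = ("married", "has_children", "phone_self_owned",
                  "baseline_consistent", "outcome_wk3", "outcome_wk6")
_INT_FIELDS = ("age", "household_size")


@dataclass
class ParticipantRecord:
    """A single driver's roster row.

    ``baseline_consistent`` is required (it defines the randomization
    strata); every other covariate and outcome may be missing. ``arm`` is
    ``None`` until randomization assigns it.
    """

    id: str
    baseline_consistent: int
    district: Optional[str] = None
    age: Optional[int] = None
    education: Optional[str] = None
    married: Optional[int] = None
    has_children: Optional[int] = None
    phone_self_owned: Optional[int] = None
    household_size: Optional[int] = None
    driving_setting: Optional[str] = None
    night_freq: Optional[str] = None
    speeding_freq: Optional[str] = None
    weekend_freq: Optional[str] = None
    arm: Optional[str] = None
    outcome_wk3: Optional[int] = None
    outcome_wk6: Optional[int] = None

    @property
    def stratum(self) -> str:
        return "consistent" if self.baseline_consistent else "inconsistent"

    def with_arm(self, arm: str) -> "ParticipantRecord":
        if self.arm is not None and self.arm != arm:
            raise ValueError(
                f"record {self.id!r} already assigned to arm {self.arm!r}")
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
        return replace(self, arm=arm)


@dataclass(frozen=True)
class CountTable:
    """A labelled table of nonnegative integer counts (rows x columns)."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def cell(self, row, col) -> int:
        return int(self.counts[self.row_labels.index(row),
                               self.col_labels.index(col)])

    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-event counts: a/b exposed event/non-event, c/d reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_reference(self) -> int:
        return self.c + self.d


def _parse_cell(value: str, column: str, row_number: int):
    if value == "":
        return None
    if column in _CATEGORICAL_LEVELS:
        if value not in _CATEGORICAL_LEVELS[column]:
            raise ValueError(
                f"row {row_number}, column {column!r}: unknown level "
                f"{value!r}; expected one of {_CATEGORICAL_LEVELS[column]}")
        return value
    if column in _BINARY_FIELDS:
        if value not in ("0", "1"):
            raise ValueError(
                f"row {row_number}, column {column!r}: expected 0/1, "
                f"got {value!r}")
        return int(value)
    if column in _INT_FIELDS:
        try:
            parsed = int(float(value))
        except ValueError:
            raise ValueError(
                f"row {row_number}, column {column!r}: expected an "
                f"integer, got {value!r}") from None
        if parsed < 0:
            raise ValueError(
                f"row {row_number}, column {column!r}: negative value")
        return parsed
    return value


def read_trial_csv(path) -> list[ParticipantRecord]:
    """Read a roster CSV into records, preserving row order and missingness.

    Unknown columns are ignored with a logged warning. Empty cells become
    ``None``; any other sentinel for missingness is rejected by the
    per-column parsers. A missing ``baseline_consistent`` is an error.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
        frame = frame.drop(columns=unknown)
    missing_cols = [c for c in ("id", "baseline_consistent")
                    if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"roster is missing required columns: {missing_cols}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        values = {}
        for col, raw in zip(frame.columns, row):
            values[col] = _parse_cell(str(raw).strip(), col, i)
        if values.get("id") is None:
            raise ValueError(f"row {i}: empty id")
        if values.get("baseline_consistent") is None:
            raise ValueError(
                f"row {i}: baseline_consistent is required (defines strata)")
        records.append(ParticipantRecord(**values))
    return records


def write_trial_csv(records: Iterable[ParticipantRecord], path) -> None:
    """Write records as UTF-8 comma-delimited text; missing fields as empty."""
    frame = to_frame(records)
    for col in (*_BINARY_FIELDS, *_INT_FIELDS):
        frame[col] = frame[col].astype("Int64")  # ints survive missingness
    frame.to_csv(path, index=False)


def to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Records -> DataFrame in schema column order (None preserved as NaN)."""
    rows = [{f.name: getattr(r, f.name) for f in fields(ParticipantRecord)}
            for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return frame


def from_frame(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for _, row in frame.iterrows():
        values = {}
        for col in COLUMNS:
            if col not in frame.columns:
                continue
            v = row[col]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                values[col] = None
            elif col in _BINARY_FIELDS or col in _INT_FIELDS:
                values[col] = int(v)
            else:
                values[col] = v
        records.append(ParticipantRecord(**values))
    return records


def subgroup_mask(records: Sequence[ParticipantRecord],
                  subgroup: str) -> np.ndarray:
    """Boolean mask for ``all`` / ``baseline_consistent`` / ``baseline_inconsistent``."""
    if subgroup == "all":
        return np.ones(len(records), dtype=bool)
    if subgroup in ("baseline_consistent", "consistent"):
        return np.array([r.baseline_consistent == 1 for r in records])
    if subgroup in ("baseline_inconsistent", "inconsistent"):
        return np.array([r.baseline_consistent == 0 for r in records])
    raise ValueError(f"unknown subgroup {subgroup!r}")
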