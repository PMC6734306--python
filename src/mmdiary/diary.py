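"""Daily headache-diary data structures, menstrual-window detection, and CSV I/O.

A diary is one subject's ordered sequence of days, each flagged for migraine
and for menstrual bleeding.  Day indices are 1-based and consecutive.  The
menstrual window anchored at a bleeding onset spans the five days
``onset - 2 .. onset + 2`` (two days before the first bleeding day through the
third day of bleeding), clipped at the diary boundaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: half-width of the menstrual window around the bleeding onset day
WINDOW_HALF_WIDTH = 2

CSV_COLUMNS = ("subject_id", "day_index", "migraine", "bleeding")


class DiaryParseError(ValueError):
    """Raised when a diary CSV stream cannot be parsed."""


@dataclass(frozen=True)
class DayRecord:
    """One diary day: 1-based ordinal plus the two boolean flags."""

    day_index: int
    migraine: bool
    bleeding: bool


@dataclass(frozen=True)
class MenstrualWindow:
    """The 5-day menstrual window anchored at a bleeding onset.

    ``days`` holds the member day indices in order; a window clipped by the
    diary extent (or whose onset falls on the diary's first day, where the
    onset itself is unobservable) is flagged ``partial``.
    """

    onset_day: int
    days: tuple[int, ...]
    partial: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.days) <= 5:
            raise ValueError("a menstrual window holds between 1 and 5 days")
        if self.onset_day not in self.days:
            raise ValueError("window must contain its onset day")


class Diary:
    """One subject's diary as parallel boolean day arrays.

    Day indices are implicit: day ``i`` (1-based) is position ``i - 1`` of the
    ``migraine`` / ``bleeding`` arrays.
    """

    def __init__(
        self,
        subject_id: str,
        migraine: Sequence[bool] | np.ndarray,
        bleeding: Sequence[bool] | np.ndarray,
        meta: dict | None = None,
    ) -> None:
        self.subject_id = str(subject_id)
        self.migraine = np.asarray(migraine, dtype=bool).copy()
        self.bleeding = np.asarray(bleeding, dtype=bool).copy()
        if self.migraine.ndim != 1 or self.migraine.shape != self.bleeding.shape:
            raise ValueError("migraine and bleeding must be 1-d arrays of equal length")
        if self.migraine.size == 0:
            raise ValueError(f"diary {subject_id!r} is empty")
        self.meta = dict(meta) if meta else {}

    # -- construction / views -------------------------------------------------

    @classmethod
    def from_days(
        cls, subject_id: str, days: Iterable[DayRecord], meta: dict | None = None
    ) -> "Diary":
        days = list(days)
        indices = [d.day_index for d in days]
        if indices != list(range(1, len(days) + 1)):
            raise ValueError(
                f"diary {subject_id!r}: day_index must be consecutive from 1"
            )
        return cls(
            subject_id,
            [d.migraine for d in days],
            [d.bleeding for d in days],
            meta=meta,
        )

    @property
    def n_days(self) -> int:
        return int(self.migraine.size)

    @property
    def days(self) -> list[DayRecord]:
        return [
            DayRecord(i + 1, bool(m), bool(b))
            for i, (m, b) in enumerate(zip(self.migraine, self.bleeding))
        ]

    def __len__(self) -> int:
        return self.n_days

    def __iter__(self) -> Iterator[DayRecord]:
        return iter(self.days)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diary):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and np.array_equal(self.migraine, other.migraine)
            and np.array_equal(self.bleeding, other.bleeding)
            and self.meta == other.meta
        )

    def __repr__(self) -> str:
        return (
            f"Diary({self.subject_id!r}, n_days={self.n_days}, "
            f"migraine_days={int(self.migraine.sum())}, "
            f"bleeding_days={int(self.bleeding.sum())})"
        )

    def slice_days(self, first: int, last: int) -> "Diary":
        """Sub-diary of days ``first..last`` (1-based, inclusive), re-anchored to 1."""
        if not 1 <= first <= last <= self.n_days:
            raise ValueError(f"invalid day range {first}..{last} for {self.n_days}-day diary")
        return Diary(
            self.subject_id,
            self.migraine[first - 1 : last],
            self.bleeding[first - 1 : last],
            meta=self.meta,
        )

    def replace(self, migraine: np.ndarray | None = None) -> "Diary":
        """Copy with the migraine flags replaced (used by imputation)."""
        return Diary(
            self.subject_id,
            self.migraine if migraine is None else migraine,
            self.bleeding,
            meta=self.meta,
        )


# -- menstrual windows --------------------------------------------------------


def bleeding_onsets(diary: Diary) -> np.ndarray:
    """1-based day indices of bleeding onsets.

    An onset is a bleeding day whose immediately preceding diary day is
    non-bleeding; the diary's first day counts as an onset if bleeding.
    Consecutive bleeding days belong to one bleed.
    """
    b = diary.bleeding
    prev = np.concatenate(([False], b[:-1]))
    return np.flatnonzero(b & ~prev) + 1


def detect_windows(diary: Diary) -> list[MenstrualWindow]:
    """One :class:`MenstrualWindow` per bleeding onset, in diary order.

    Windows clipped at the diary boundaries — including an onset on day 1,
    where the true onset day is unobservable — are flagged ``partial``.
    """
    windows = []
    for onset in bleeding_onsets(diary):
        onset = int(onset)
        lo = max(1, onset - WINDOW_HALF_WIDTH)
        hi = min(diary.n_days, onset + WINDOW_HALF_WIDTH)
        partial = (hi - lo + 1) < 5 or onset == 1
        windows.append(MenstrualWindow(onset, tuple(range(lo, hi + 1)), partial))
    return windows


def window_day_mask(diary: Diary, windows: Sequence[MenstrualWindow]) -> np.ndarray:
    """Boolean mask (0-based) of days belonging to any window (set union)."""
    mask = np.zeros(diary.n_days, dtype=bool)
    for w in windows:
        for d in w.days:
            mask[d - 1] = True
    return mask


# -- CSV I/O ------------------------------------------------------------------


def _parse_flag(value, column: str, line: int) -> bool:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        iv = -1
    if iv not in (0, 1):
        raise DiaryParseError(f"line {line}: column {column!r} must be 0 or 1, got {value!r}")
    return bool(iv)


def read_diaries(source: str | IO[str]) -> list[Diary]:
    """Read diaries from a CSV stream (``subject_id,day_index,migraine,bleeding[,age]``).

    Returns one :class:`Diary` per subject, in order of first appearance.
    Subjects whose day indices are not consecutive from 1 are rejected with a
    logged reason; malformed rows raise :class:`DiaryParseError` naming the
    line number.
    """
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as exc:
        raise DiaryParseError(f"malformed diary CSV: {exc}") from exc

    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DiaryParseError(f"missing required columns: {', '.join(missing)}")
    if frame.empty:
        return []

    has_age = "age" in frame.columns
    diaries: list[Diary] = []
    for subject_id, rows in frame.groupby("subject_id", sort=False):
        rows = rows.sort_values("day_index")
        lines = rows.index.to_numpy() + 2  # header + 1-based file lines
        try:
            idx = rows["day_index"].astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise DiaryParseError(f"subject {subject_id!r}: non-integer day_index") from exc
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            logger.warning(
                "rejecting subject %r: day_index not consecutive from 1", subject_id
            )
            continue
        mig = [
            _parse_flag(v, "migraine", ln) for v, ln in zip(rows["migraine"], lines)
        ]
        ble = [
            _parse_flag(v, "bleeding", ln) for v, ln in zip(rows["bleeding"], lines)
        ]
        meta = {}
        if has_age:
            ages = rows["age"].dropna().unique()
            if len(ages):
                meta["age"] = float(ages[0])
        diaries.append(Diary(str(subject_id), mig, ble, meta=meta))
    return diaries


def write_diaries(diaries: Sequence[Diary], sink: str | IO[str]) -> None:
    """Write diaries as CSV so that :func:`read_diaries` round-trips exactly."""
    any_age = any("age" in d.meta for d in diaries)
    records = []
    for d in diaries:
        for rec in d.days:
            row = {
                "subject_id": d.subject_id,
                "day_index": rec.day_index,
                "migraine": int(rec.migraine),
                "bleeding": int(rec.bleeding),
            }
            if any_age:
                row["age"] = d.meta.get("age", "")
            records.append(row)
    columns = list(CSV_COLUMNS) + (["age"] if any_age else [])
    pd.DataFrame(records, columns=columns).to_csv(sink, index=False)
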