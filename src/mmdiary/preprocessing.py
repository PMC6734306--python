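"""Diary eligibility filters and migraine-locked-day imputation.

The cleaning pipeline applied to an observational diary before diagnosis:

1. compute menstrual cycle lengths (onset-to-onset, in days);
2. drop cycles longer than twice the subject's mean cycle length (taken to be
   missing data) and keep the longest remaining run of at least three
   consecutive valid cycles, excluding the diary if no such run exists;
3. eligibility: at least three consecutive valid cycles;
4. truncate the diary 15 days before the first and 15 days after the last
   registered bleeding day, re-anchoring day 1;
5. impute migraine onto migraine-locked days (non-migraine days immediately
   preceded and succeeded by migraine days), to a fixed point.

Steps 2-4 exist to guard against missing data in self-kept diaries; step 5 is
part of the attack model itself (a single headache-free day between migraine
days is treated as part of one attack).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diary import Diary, bleeding_onsets

#: days retained on either side of the first/last registered bleeding
TRUNCATION_MARGIN = 15

#: minimum number of consecutive valid cycles for an analysable diary
MIN_CONSECUTIVE_CYCLES = 3

#: a cycle longer than this multiple of the subject mean is treated as missing data
ATYPICAL_FACTOR = 2.0


@dataclass(frozen=True)
class CycleRecord:
    """One menstrual cycle: the span between two consecutive bleeding onsets."""

    start_onset: int
    end_onset: int

    @property
    def length_days(self) -> int:
        return self.end_onset - self.start_onset

    def __post_init__(self) -> None:
        if self.end_onset <= self.start_onset:
            raise ValueError("cycle must end after it starts")


@dataclass
class PreprocessReport:
    """Bookkeeping for one subject's pass through the cleaning pipeline."""

    subject_id: str
    excluded: bool = False
    exclusion_reason: str = "none"  # none | too_few_cycles | atypical_unsalvageable
    retained_day_range: tuple[int, int] | None = None
    imputed_locked_days: int = 0

    def __post_init__(self) -> None:
        if self.excluded and self.exclusion_reason == "none":
            raise ValueError("an excluded diary needs an exclusion reason")

    def log_line(self) -> str:
        status = f"EXCLUDED ({self.exclusion_reason})" if self.excluded else "eligible"
        rng = (
            f"days {self.retained_day_range[0]}-{self.retained_day_range[1]}"
            if self.retained_day_range
            else "-"
        )
        return (
            f"{self.subject_id}: {status}; retained {rng}; "
            f"imputed locked days {self.imputed_locked_days}"
        )


def cycle_lengths(diary: Diary) -> list[CycleRecord]:
    """One :class:`CycleRecord` per consecutive pair of bleeding onsets."""
    onsets = bleeding_onsets(diary)
    return [
        CycleRecord(int(a), int(b)) for a, b in zip(onsets[:-1], onsets[1:])
    ]


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs (start, stop) of True entries, as half-open index pairs."""
    runs = []
    start = None
    for i, v in enumerate(valid):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(valid)))
    return runs


def _bleed_end(diary: Diary, onset: int) -> int:
    """Last day (1-based) of the bleeding episode starting at ``onset``."""
    end = onset
    while end < diary.n_days and diary.bleeding[end]:  # b[end] is day end+1
        end += 1
    return end


def drop_atypical_cycles(
    diary: Diary, cycles: Sequence[CycleRecord]
) -> tuple[Diary | None, PreprocessReport]:
    """Remove diary portions covered by atypically long cycles.

    A cycle longer than twice the subject's mean cycle length (mean over all
    of her cycles, one pass) is assumed to mark missing diary data.  The
    longest remaining run of at least three consecutive valid cycles is
    retained (ties broken toward the earliest run); if none exists the diary
    is excluded.
    """
    report = PreprocessReport(diary.subject_id)
    if not cycles:
        report.retained_day_range = (1, diary.n_days)
        return diary, report

    lengths = np.array([c.length_days for c in cycles], dtype=float)
    valid = lengths <= ATYPICAL_FACTOR * lengths.mean()
    if valid.all():
        report.retained_day_range = (1, diary.n_days)
        return diary, report

    runs = [r for r in _valid_runs(valid) if r[1] - r[0] >= MIN_CONSECUTIVE_CYCLES]
    if not runs:
        report.excluded = True
        report.exclusion_reason = "atypical_unsalvageable"
        return None, report

    start_idx, stop_idx = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    first = 1 if start_idx == 0 else cycles[start_idx].start_onset
    if stop_idx == len(cycles):
        last = diary.n_days
    else:
        close = cycles[stop_idx - 1].end_onset
        last = min(diary.n_days, max(_bleed_end(diary, close), close + 2))
    report.retained_day_range = (first, last)
    return diary.slice_days(first, last), report


def eligibility(diary: Diary) -> PreprocessReport:
    """Eligibility check: at least three consecutive valid cycles.

    Assumes atypical cycles have already been handled; a diary whose remaining
    cycles number fewer than three is excluded with reason ``too_few_cycles``.
    """
    report = PreprocessReport(diary.subject_id)
    cycles = cycle_lengths(diary)
    if len(cycles) < MIN_CONSECUTIVE_CYCLES:
        report.excluded = True
        report.exclusion_reason = "too_few_cycles"
    return report


def truncate_diary(diary: Diary) -> Diary:
    """Truncate 15 days before the first and after the last bleeding day.

    Guards against migraine days far from any observed menstruation being
    misread as non-menstrual evidence when the surrounding cycles were simply
    not recorded.  Day indices are re-anchored to 1.
    """
    bleeding_days = np.flatnonzero(diary.bleeding) + 1
    if bleeding_days.size == 0:
        raise ValueError(
            f"diary {diary.subject_id!r} has no bleeding days; not analysable"
        )
    first = max(1, int(bleeding_days[0]) - TRUNCATION_MARGIN)
    last = min(diary.n_days, int(bleeding_days[-1]) + TRUNCATION_MARGIN)
    return diary.slice_days(first, last)


def impute_locked_days(diary: Diary) -> tuple[Diary, int]:
    """Set migraine on every migraine-locked day, iterating to a fixed point.

    A migraine-locked day is a non-migraine day whose both neighbours are
    migraine days; under the attack model it belongs to a single ongoing
    attack and is imputed as a migraine day.
    """
    m = diary.migraine.copy()
    imputed = 0
    while True:
        locked = np.zeros_like(m)
        locked[1:-1] = ~m[1:-1] & m[:-2] & m[2:]
        if not locked.any():
            break
        imputed += int(locked.sum())
        m |= locked
    return diary.replace(migraine=m), imputed


def preprocess(diary: Diary) -> tuple[Diary | None, PreprocessReport]:
    """Run the full cleaning pipeline on one diary.

    Returns the cleaned diary (or ``None`` if excluded) with a
    :class:`PreprocessReport`.  Re-running the pipeline on its own output is a
    no-op.
    """
    cycles = cycle_lengths(diary)
    if len(cycles) < MIN_CONSECUTIVE_CYCLES:
        report = PreprocessReport(
            diary.subject_id, excluded=True, exclusion_reason="too_few_cycles"
        )
        return None, report
    kept, report = drop_atypical_cycles(diary, cycles)
    if kept is None:
        return None, report
    check = eligibility(kept)
    if check.excluded:
        check.retained_day_range = report.retained_day_range
        return None, check
    kept = truncate_diary(kept)
    kept, n_imputed = impute_locked_days(kept)
    report.imputed_locked_days = n_imputed
    return kept, report


def summarise_reports(reports: Sequence[PreprocessReport]) -> dict[str, int]:
    """Exclusion counts by reason plus totals, for a cohort summary table."""
    out = {
        "total": len(reports),
        "eligible": sum(not r.excluded for r in reports),
        "excluded": sum(r.excluded for r in reports),
        "too_few_cycles": sum(r.exclusion_reason == "too_few_cycles" for r in reports),
        "atypical_unsalvageable": sum(
            r.exclusion_reason == "atypical_unsalvageable" for r in reports
        ),
    }
    return out
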