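"""Markov-role classification of diary days and the 2x2 contingency counts.

The statistical criterion tests whether attack *onsets* concentrate in the
menstrual windows.  Days on which no attack could start carry no information
about the onset probability and are trimmed away:

* days on which an attack is ongoing (after its first day);
* the two days immediately following each attack's end — headache recurring
  2-48 h after initial pain freedom counts as a relapse of the same attack,
  so those days cannot host an independent onset;
* days of an attack whose start is unobservable (the run begins on the
  diary's first retained day).

The remaining days are the susceptible days plus the attack-start days; the
test's 2x2 table counts them inside/outside the menstrual windows.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diary import Diary, MenstrualWindow, window_day_mask

#: post-attack days on which a recurrence is a relapse, not a new onset
REFRACTORY_DAYS = 2


class DayState(enum.IntEnum):
    SUSCEPTIBLE = 0  # no attack; an onset could occur
    ATTACK_START = 1  # first day of an attack with an observed start
    ONGOING = 2  # attack day after the first
    REFRACTORY = 3  # one of the two days after an attack's end
    EXCLUDED = 4  # attack day whose start is unobservable


@dataclass(frozen=True)
class Attack:
    """A maximal run of consecutive migraine days (after locked-day imputation)."""

    start_day: int
    end_day: int
    identifiable_start: bool = True

    @property
    def length_days(self) -> int:
        return self.end_day - self.start_day + 1

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError("attack must end no earlier than it starts")


@dataclass(frozen=True)
class ContingencyCounts:
    """The (N, K, n, k) table feeding the exact test.

    ``untrimmed_days``: all days vs. migraine days (the older day-count
    probability criterion).  ``trimmed_onsets``: classifiable days vs.
    attack-start days (the onset-based criterion).
    """

    N: int
    K: int
    n: int
    k: int
    variant: str  # untrimmed_days | trimmed_onsets

    def __post_init__(self) -> None:
        if min(self.N, self.K, self.n, self.k) < 0:
            raise ValueError("counts must be non-negative")
        if not (self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(f"inconsistent contingency counts {self}")


def segment_attacks(diary: Diary) -> list[Attack]:
    """Maximal runs of consecutive migraine days, in order.

    Expects a locked-day-imputed diary.  A run starting on the first retained
    day has no observable onset (``identifiable_start=False``).
    """
    m = diary.migraine
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1) + 1  # 1-based day indices
    ends = np.flatnonzero(edges == -1)  # 1-based last migraine day
    return [
        Attack(int(s), int(e), identifiable_start=(s != 1))
        for s, e in zip(starts, ends)
    ]


def _merge_complexes(attacks: Sequence[Attack]) -> list[tuple[int, int, bool]]:
    """Merge attacks whose onset falls on the preceding attack's refractory days.

    A migraine day on one of the two post-attack days is a relapse of the same
    attack, so such runs form one attack complex; the refractory period
    restarts after the merged run.  On an imputed diary consecutive runs are
    at least three days apart and no merging occurs.
    """
    complexes: list[tuple[int, int, bool]] = []
    for a in attacks:
        if complexes and a.start_day <= complexes[-1][1] + REFRACTORY_DAYS:
            s, _, ident = complexes[-1]
            complexes[-1] = (s, a.end_day, ident)
        else:
            complexes.append((a.start_day, a.end_day, a.identifiable_start))
    return complexes


def classify_days(diary: Diary, attacks: Sequence[Attack] | None = None) -> np.ndarray:
    """Per-day :class:`DayState` array (0-based positions, 1-based days).

    Attack complexes (see :func:`_merge_complexes`) get an ``ATTACK_START`` on
    their first day when identifiable (``EXCLUDED`` migraine days otherwise),
    ``ONGOING`` on later migraine days, and ``REFRACTORY`` on non-migraine
    days inside the complex and on the two days after its end.  All other
    days are ``SUSCEPTIBLE``.
    """
    if attacks is None:
        attacks = segment_attacks(diary)
    states = np.full(diary.n_days, DayState.SUSCEPTIBLE, dtype=np.int8)
    m = diary.migraine
    for start, end, identifiable in _merge_complexes(attacks):
        span = slice(start - 1, end)
        mig_span = m[span]
        states[span] = np.where(mig_span, DayState.ONGOING, DayState.REFRACTORY)
        if identifiable:
            states[start - 1] = DayState.ATTACK_START
        else:
            idx = np.arange(start - 1, end)[mig_span]
            states[idx] = DayState.EXCLUDED
        tail = slice(end, min(diary.n_days, end + REFRACTORY_DAYS))
        states[tail] = DayState.REFRACTORY
    return states


def untrimmed_counts(
    diary: Diary, windows: Sequence[MenstrualWindow]
) -> ContingencyCounts:
    """Day-based table: all days (N), window days (K), migraine days (n, k)."""
    win = window_day_mask(diary, windows)
    m = diary.migraine
    return ContingencyCounts(
        N=diary.n_days,
        K=int(win.sum()),
        n=int(m.sum()),
        k=int((m & win).sum()),
        variant="untrimmed_days",
    )


def trimmed_counts(
    diary: Diary,
    windows: Sequence[MenstrualWindow],
    states: np.ndarray | None = None,
) -> ContingencyCounts:
    """Onset-based table over the classifiable (susceptible + attack-start) days.

    Window membership is evaluated on the day's original index within the
    diary; trimming removes days from the counts, it does not renumber.
    """
    if states is None:
        states = classify_days(diary)
    win = window_day_mask(diary, windows)
    classifiable = (states == DayState.SUSCEPTIBLE) | (states == DayState.ATTACK_START)
    onset = states == DayState.ATTACK_START
    if not classifiable.any():
        raise ValueError(
            f"diary {diary.subject_id!r}: no classifiable days after trimming"
        )
    return ContingencyCounts(
        N=int(classifiable.sum()),
        K=int((classifiable & win).sum()),
        n=int(onset.sum()),
        k=int((onset & win).sum()),
        variant="trimmed_onsets",
    )
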