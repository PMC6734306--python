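"""The two diagnostic criteria and Markov-parameter estimation.

* sMM(alpha) — *statistical menstrual migraine*: positive when the trimmed
  diary's one-sided mid-p value is below alpha (any alpha < 0.5 defines a
  member of the family; 0.1 is the conventional default).  Its specificity is
  1 - alpha by construction.
* The 2/3-criterion — the classification-appendix rule: positive when a
  migraine attack started within at least two thirds of the recorded
  menstrual windows (onset-based; at least three windows required).

Markov parameters are estimated from the trimmed classification:
``mu = n/N`` (onset probability per classifiable day), ``mu_M = k/K`` inside
windows, ``mu_NM = (n-k)/(N-K)`` outside, and the attack-continuation
probability ``delta`` from observed attack run lengths (continuation events
per migraine day in identifiable attacks).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diary import Diary, MenstrualWindow, detect_windows
from .exact_test import MidPValue, midp_value
from .preprocessing import impute_locked_days
from .trimming import (
    Attack,
    DayState,
    classify_days,
    segment_attacks,
    trimmed_counts,
)

#: canonical window fraction of the classification-appendix rule
TWO_THIRDS = 2.0 / 3.0

#: windows needed before the 2/3-criterion is assessable
MIN_WINDOWS = 3

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class MarkovParams:
    """Per-day transition probabilities of the attack chain.

    ``mu`` is the flat onset probability, ``mu_nm``/``mu_m`` the onset
    probabilities outside/inside menstrual windows, ``delta`` the probability
    that an ongoing attack continues one more day.  Fields that cannot be
    estimated (e.g. ``mu_m`` when no classifiable window days exist) are NaN.
    """

    mu: float
    mu_nm: float
    mu_m: float
    delta: float

    @property
    def delta_mu(self) -> float:
        return self.mu_m - self.mu_nm

    def __post_init__(self) -> None:
        for name in ("mu", "mu_nm", "mu_m", "delta"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")

    @classmethod
    def flat(cls, mu: float, delta: float) -> "MarkovParams":
        """Null-model parameters: identical onset probability on every day."""
        return cls(mu=mu, mu_nm=mu, mu_m=mu, delta=delta)


@dataclass
class DiagnosisResult:
    """Verdicts of both criteria for one subject."""

    subject_id: str
    smm_p: MidPValue
    alpha: float
    smm_positive: bool
    windows_total: int
    windows_with_onset: int
    two_thirds_positive: bool
    two_thirds_assessable: bool

    @property
    def onset_window_fraction(self) -> float:
        if self.windows_total == 0:
            return math.nan
        return self.windows_with_onset / self.windows_total


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")


def windows_with_onset(
    diary: Diary,
    windows: Sequence[MenstrualWindow],
    states: np.ndarray | None = None,
) -> int:
    """Number of menstrual windows containing at least one attack-start day."""
    if states is None:
        states = classify_days(diary)
    return sum(
        any(states[d - 1] == DayState.ATTACK_START for d in w.days) for w in windows
    )


def two_thirds_diagnose(
    diary: Diary,
    windows: Sequence[MenstrualWindow] | None = None,
    states: np.ndarray | None = None,
    threshold: float = TWO_THIRDS,
) -> tuple[int, int, bool, bool]:
    """(windows_total, windows_with_onset, positive, assessable) for the 2/3 rule.

    Positive when the fraction of windows containing an attack onset is at
    least ``threshold``; not assessable with fewer than three windows (the
    verdict is then negative).
    """
    if windows is None:
        windows = detect_windows(diary)
    if states is None:
        states = classify_days(diary)
    total = len(windows)
    hits = windows_with_onset(diary, windows, states)
    assessable = total >= MIN_WINDOWS
    positive = assessable and total > 0 and (hits / total) >= threshold
    return total, hits, positive, assessable


def smm_diagnose(
    diary: Diary,
    alpha: float = DEFAULT_ALPHA,
    impute: bool = True,
) -> DiagnosisResult:
    """Full diagnosis of one (preprocessed) diary under both criteria.

    Applies locked-day imputation (idempotent) unless ``impute=False``, trims
    the diary to its classifiable days, computes the one-sided mid-p value
    and both verdicts.  A non-evaluable table yields ``smm_positive=False``
    with the p-value flagged.
    """
    _check_alpha(alpha)
    if impute:
        diary, _ = impute_locked_days(diary)
    windows = detect_windows(diary)
    states = classify_days(diary)
    counts = trimmed_counts(diary, windows, states)
    p = midp_value(counts)
    positive = p.evaluable and p.p < alpha
    total, hits, tt_positive, assessable = two_thirds_diagnose(diary, windows, states)
    return DiagnosisResult(
        subject_id=diary.subject_id,
        smm_p=p,
        alpha=alpha,
        smm_positive=positive,
        windows_total=total,
        windows_with_onset=hits,
        two_thirds_positive=tt_positive,
        two_thirds_assessable=assessable,
    )


#: alias: `smm_diagnose` runs both criteria
diagnose = smm_diagnose


def estimate_params(
    diary: Diary,
    windows: Sequence[MenstrualWindow] | None = None,
    states: np.ndarray | None = None,
    attacks: Sequence[Attack] | None = None,
) -> MarkovParams:
    """Estimate (mu, mu_NM, mu_M, delta) from a trimmed diary.

    The mu's are onset frequencies over the classifiable days (all / outside
    windows / inside windows); delta is the continuation frequency per
    migraine day within identifiable attacks, i.e. the plug-in estimate under
    geometric attack durations (mean duration 1/(1-delta)).  Undefined ratios
    (zero denominator) are NaN.
    """
    if windows is None:
        windows = detect_windows(diary)
    if states is None:
        states = classify_days(diary)
    if attacks is None:
        attacks = segment_attacks(diary)
    counts = trimmed_counts(diary, windows, states)
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    mu = n / N if N else math.nan
    mu_m = k / K if K else math.nan
    mu_nm = (n - k) / (N - K) if N - K else math.nan
    identifiable = [a for a in attacks if a.identifiable_start]
    mig_days = sum(a.length_days for a in identifiable)
    delta = (mig_days - len(identifiable)) / mig_days if mig_days else math.nan
    return MarkovParams(mu=mu, mu_nm=mu_nm, mu_m=mu_m, delta=delta)
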