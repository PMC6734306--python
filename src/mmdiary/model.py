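"""Model/Results interface for fitting the attack chain to one subject's diary.

:class:`MenstrualMigraineModel` wraps the whole per-subject procedure —
locked-day imputation, window detection, Markov-role trimming, the one-sided
mid-p exact test, both diagnostic criteria and the transition-probability
estimates — behind a ``fit()`` that returns a
:class:`MenstrualMigraineResults` carrying estimates, standard errors,
diagnostics and a text ``summary()``.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import criteria, preprocessing, trimming
from .diary import Diary, detect_windows
from .exact_test import midp_value
from .simulator import DiaryLayout, simulate_diary


class MenstrualMigraineModel:
    """Two-state attack chain with menstrually modulated onset probability.

    Parameters
    ----------
    diary
        One subject's diary.  By default the data-cleaning pipeline (atypical
        cycle removal, eligibility, truncation, locked-day imputation) is
        applied at fit time; pass ``preprocess=False`` for already-clean data
        (e.g. simulator output), in which case only the idempotent locked-day
        imputation runs.
    """

    def __init__(self, diary: Diary, preprocess: bool = True) -> None:
        self.diary = diary
        self.preprocess = preprocess

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, subject_id: str | None = None, **kwargs
    ) -> "MenstrualMigraineModel":
        """Build from a long-format frame (``subject_id,day_index,migraine,bleeding``)."""
        if subject_id is not None:
            data = data[data["subject_id"] == subject_id]
        if data.empty:
            raise ValueError(f"no rows for subject {subject_id!r}")
        ids = data["subject_id"].unique()
        if len(ids) != 1:
            raise ValueError("frame holds several subjects; pass subject_id")
        data = data.sort_values("day_index")
        diary = Diary(
            str(ids[0]),
            data["migraine"].astype(int).to_numpy().astype(bool),
            data["bleeding"].astype(int).to_numpy().astype(bool),
        )
        return cls(diary, **kwargs)

    def fit(self, alpha: float = criteria.DEFAULT_ALPHA) -> "MenstrualMigraineResults":
        if self.preprocess:
            cleaned, report = preprocessing.preprocess(self.diary)
            if cleaned is None:
                raise ValueError(
                    f"diary {self.diary.subject_id!r} excluded by preprocessing "
                    f"({report.exclusion_reason})"
                )
        else:
            cleaned, n_imputed = preprocessing.impute_locked_days(self.diary)
            report = preprocessing.PreprocessReport(
                self.diary.subject_id, imputed_locked_days=n_imputed
            )
        return MenstrualMigraineResults(self, cleaned, report, alpha)


class MenstrualMigraineResults:
    """Fitted per-subject results: counts, estimates, test, diagnoses."""

    def __init__(
        self,
        model: MenstrualMigraineModel,
        diary: Diary,
        report: preprocessing.PreprocessReport,
        alpha: float,
    ) -> None:
        self.model = model
        self.diary = diary
        self.preprocess_report = report
        self.alpha = alpha

        self.windows = detect_windows(diary)
        self.attacks = trimming.segment_attacks(diary)
        self.day_states = trimming.classify_days(diary, self.attacks)
        self.counts = trimming.trimmed_counts(diary, self.windows, self.day_states)
        self.counts_untrimmed = trimming.untrimmed_counts(diary, self.windows)
        self.midp = midp_value(self.counts)
        self.midp_untrimmed = midp_value(self.counts_untrimmed)
        self.params = criteria.estimate_params(
            diary, self.windows, self.day_states, self.attacks
        )
        self.diagnosis = criteria.smm_diagnose(diary, alpha=alpha, impute=False)

    # -- uncertainties --------------------------------------------------------

    @property
    def bse(self) -> dict[str, float]:
        """Binomial standard errors of the estimated transition probabilities."""
        c = self.counts
        p = self.params
        mig_days = sum(a.length_days for a in self.attacks if a.identifiable_start)

        def se(prob: float, denom: int) -> float:
            if denom == 0 or math.isnan(prob):
                return math.nan
            return math.sqrt(prob * (1.0 - prob) / denom)

        return {
            "mu": se(p.mu, c.N),
            "mu_nm": se(p.mu_nm, c.N - c.K),
            "mu_m": se(p.mu_m, c.K),
            "delta": se(p.delta, mig_days),
        }

    @property
    def pvalue(self) -> float:
        """The one-sided mid-p value (NaN when not evaluable)."""
        return self.midp.p if self.midp.evaluable else math.nan

    # -- simulation -----------------------------------------------------------

    def simulate(
        self,
        layout: DiaryLayout | None = None,
        seed: int | np.random.Generator | None = None,
        subject_id: str | None = None,
    ) -> Diary:
        """Parametric re-simulation: a diary from the fitted chain parameters."""
        p = self.params
        if any(math.isnan(getattr(p, f)) for f in ("mu_nm", "mu_m", "delta")):
            raise ValueError("cannot simulate: some parameters are not estimable")
        layout = layout or DiaryLayout(n_cycles=max(3, len(self.windows)))
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return simulate_diary(
            p, layout, rng, subject_id=subject_id or f"{self.diary.subject_id}-sim"
        )

    # -- presentation ---------------------------------------------------------

    def row(self) -> dict:
        """Flat per-subject record (the CLI's table row)."""
        d = self.diagnosis
        return {
            "subject_id": self.diary.subject_id,
            "N": self.counts.N,
            "K": self.counts.K,
            "n": self.counts.n,
            "k": self.counts.k,
            "p": self.pvalue,
            "smm_positive": d.smm_positive,
            "windows_total": d.windows_total,
            "windows_with_onset": d.windows_with_onset,
            "two_thirds_positive": d.two_thirds_positive,
            "mu": self.params.mu,
            "mu_nm": self.params.mu_nm,
            "mu_m": self.params.mu_m,
            "delta": self.params.delta,
        }

    def summary(self) -> str:
        c, cu, p, se = self.counts, self.counts_untrimmed, self.params, self.bse
        d = self.diagnosis

        def fmt(v: float) -> str:
            return "   NA" if math.isnan(v) else f"{v:.3f}"

        lines = [
            "          Menstrual Migraine Attack-Chain Results",
            "=" * 58,
            f"Subject: {self.diary.subject_id:<22} Diary days: {self.diary.n_days}",
            f"Menstrual windows: {len(self.windows):<12} Attacks (identifiable): "
            f"{sum(a.identifiable_start for a in self.attacks)}",
            "-" * 58,
            "Contingency counts          N      K      n      k",
            f"  trimmed (onsets)     {c.N:6d} {c.K:6d} {c.n:6d} {c.k:6d}",
            f"  untrimmed (days)     {cu.N:6d} {cu.K:6d} {cu.n:6d} {cu.k:6d}",
            "-" * 58,
            "Transition probabilities (per day)     estimate     SE",
            f"  mu      (onset, all days)            {fmt(p.mu):>8} {fmt(se['mu']):>7}",
            f"  mu_NM   (onset, outside windows)     {fmt(p.mu_nm):>8} {fmt(se['mu_nm']):>7}",
            f"  mu_M    (onset, inside windows)      {fmt(p.mu_m):>8} {fmt(se['mu_m']):>7}",
            f"  delta   (attack continuation)        {fmt(p.delta):>8} {fmt(se['delta']):>7}",
            f"  delta_mu = mu_M - mu_NM              {fmt(p.delta_mu):>8}",
            "-" * 58,
            f"One-sided mid-p (trimmed):   {fmt(self.pvalue)}"
            + ("" if self.midp.evaluable else "  (not evaluable)"),
            f"sMM({self.alpha:g}):                    "
            + ("POSITIVE" if d.smm_positive else "negative"),
            f"2/3-criterion ({d.windows_with_onset}/{d.windows_total} windows "
            f"with onset): " + ("POSITIVE" if d.two_thirds_positive else "negative")
            + ("" if d.two_thirds_assessable else " (not assessable, <3 windows)"),
            "=" * 58,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MenstrualMigraineResults subject={self.diary.subject_id!r} "
            f"p={self.pvalue:.4g} alpha={self.alpha}>"
        )


def fit_cohort(
    diaries: Sequence[Diary], alpha: float = criteria.DEFAULT_ALPHA
) -> tuple[list[MenstrualMigraineResults], list[preprocessing.PreprocessReport]]:
    """Fit every eligible diary of a cohort; collect exclusion reports."""
    results: list[MenstrualMigraineResults] = []
    reports: list[preprocessing.PreprocessReport] = []
    for diary in diaries:
        cleaned, report = preprocessing.preprocess(diary)
        reports.append(report)
        if cleaned is None:
            continue
        results.append(
            MenstrualMigraineModel(cleaned, preprocess=False).fit(alpha=alpha)
        )
    return results, reports
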