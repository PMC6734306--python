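"""ROC/AUC simulation study comparing the sMM and 2/3 criteria.

Two labelled arms are simulated from the attack chain (true positives with
menstrually elevated onset probability, true negatives without), every diary
is pushed through the imputation + trimming + testing pipeline, and each
criterion's ROC curve is traced: the sMM by sweeping the significance level
alpha applied to the mid-p value, the 2/3-criterion by sweeping the required
fraction of windows containing an attack onset (its canonical 2/3 operating
point is reported separately).  The study is repeated across diary lengths of
3 to 9 menstrual cycles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .criteria import TWO_THIRDS, DEFAULT_ALPHA, smm_diagnose
from .simulator import DiaryLayout, LabelledPopulation, PopulationSpec, sample_population


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    sensitivity_se: float
    specificity_se: float


@dataclass
class CriterionPerformance:
    """ROC summary of one criterion at one diary length."""

    n_cycles: int
    criterion: str  # smm | two_thirds
    operating_points: list[OperatingPoint]
    auc: float
    canonical: OperatingPoint | None = None


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under ROC points given as (fpr, tpr) pairs.

    Points are sorted along the ROC path (by fpr, then tpr), duplicates
    collapsed, and (0,0)/(1,1) anchors added if absent.  Vertical segments
    (tied fpr) contribute no area, as in the usual empirical ROC.
    """
    pts = sorted(set((float(f), float(t)) for f, t in points))
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if xs[0] > 0.0 or ys[0] > 0.0:
        xs.insert(0, 0.0)
        ys.insert(0, 0.0)
    if xs[-1] < 1.0 or ys[-1] < 1.0:
        xs.append(1.0)
        ys.append(1.0)
    return float(np.trapezoid(ys, xs))


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n)) if n else float("nan")


def _roc_points(
    score_pos: np.ndarray,
    score_neg: np.ndarray,
    thresholds: Iterable[float],
    positive_if,
) -> list[OperatingPoint]:
    pts = []
    n_pos, n_neg = len(score_pos), len(score_neg)
    for t in thresholds:
        sens = float(positive_if(score_pos, t).mean())
        fpr = float(positive_if(score_neg, t).mean())
        pts.append(
            OperatingPoint(
                threshold=float(t),
                sensitivity=sens,
                specificity=1.0 - fpr,
                sensitivity_se=_binom_se(sens, n_pos),
                specificity_se=_binom_se(1.0 - fpr, n_neg),
            )
        )
    return pts


def _performance(pts: Sequence[OperatingPoint], n_cycles: int, criterion: str,
                 canonical: OperatingPoint | None) -> CriterionPerformance:
    area = auc([(1.0 - p.specificity, p.sensitivity) for p in pts])
    ordered = sorted(pts, key=lambda p: (1.0 - p.specificity, p.sensitivity))
    return CriterionPerformance(n_cycles, criterion, list(ordered), area, canonical)


def evaluate_population(
    population: LabelledPopulation,
    n_cycles: int,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[CriterionPerformance, CriterionPerformance]:
    """Diagnose every diary and trace both criteria's ROC curves."""
    p_values = np.empty(len(population.diaries))
    fractions = np.empty(len(population.diaries))
    for i, diary in enumerate(population.diaries):
        result = smm_diagnose(diary, alpha=alpha)
        # a non-evaluable table can never reject: treat as p = 1
        p_values[i] = result.smm_p.p if result.smm_p.evaluable else 1.0
        total = result.windows_total
        fractions[i] = result.windows_with_onset / total if total else 0.0

    labels = population.labels
    p_pos, p_neg = p_values[labels], p_values[~labels]
    f_pos, f_neg = fractions[labels], fractions[~labels]

    # sMM: positive iff p < alpha; sweep alpha over the observed p values
    thr = np.unique(np.concatenate([p_values, [0.0, 1.0]]))
    smm_pts = _roc_points(p_pos, p_neg, thr, lambda s, t: s < t)
    smm_canon = _roc_points(p_pos, p_neg, [alpha], lambda s, t: s < t)[0]
    smm = _performance(smm_pts, n_cycles, "smm", smm_canon)

    # 2/3-criterion: positive iff onset-window fraction >= threshold
    thr = np.unique(np.concatenate([fractions, [0.0, 1.0, 1.0 + 1e-9]]))
    tt_pts = _roc_points(f_pos, f_neg, thr, lambda s, t: s >= t)
    tt_canon = _roc_points(f_pos, f_neg, [TWO_THIRDS], lambda s, t: s >= t)[0]
    two_thirds = _performance(tt_pts, n_cycles, "two_thirds", tt_canon)
    return smm, two_thirds


def roc_study(
    spec: PopulationSpec,
    cycle_range: Iterable[int] = range(3, 10),
    layout_template: DiaryLayout | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[CriterionPerformance]:
    """Run the full two-criterion study across diary lengths.

    Returns two :class:`CriterionPerformance` entries (sMM, 2/3) per cycle
    count.  Each cycle count uses an independent sub-seed derived from
    ``spec.seed`` so arms are reproducible individually.
    """
    template = layout_template or DiaryLayout()
    results: list[CriterionPerformance] = []
    for n_cycles in cycle_range:
        layout = DiaryLayout(
            n_cycles=n_cycles,
            cycle_length_days=template.cycle_length_days,
            window_offset=template.window_offset,
            tail_days=template.tail_days,
        )
        sub = PopulationSpec(
            n_diaries=spec.n_diaries,
            positive_params=spec.positive_params,
            negative_params=spec.negative_params,
            seed=(spec.seed * 1009 + n_cycles) % (2**31),
        )
        population = sample_population(sub, layout)
        results.extend(evaluate_population(population, n_cycles, alpha=alpha))
    return results


def performance_table(results: Sequence[CriterionPerformance]):
    """Flatten study results to a DataFrame (one row per operating point)."""
    import pandas as pd

    rows = []
    for perf in results:
        for pt in perf.operating_points:
            rows.append(
                {
                    "criterion": perf.criterion,
                    "n_cycles": perf.n_cycles,
                    "threshold": pt.threshold,
                    "sensitivity": pt.sensitivity,
                    "specificity": pt.specificity,
                    "sensitivity_se": pt.sensitivity_se,
                    "specificity_se": pt.specificity_se,
                    "auc": perf.auc,
                }
            )
    return pd.DataFrame(rows)
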