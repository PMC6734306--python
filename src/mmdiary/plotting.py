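"""Plot helpers for the ROC study and the alpha sweep (matplotlib, Agg-safe)."""
from __future__ import annotations

from typing import Sequence

from .evaluation import CriterionPerformance


def _get_axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    return ax


def plot_roc(results: Sequence[CriterionPerformance], path: str | None = None, ax=None):
    """ROC curves for both criteria, one shade per diary length (cycles)."""
    ax = _get_axes(ax)
    cycle_counts = sorted({r.n_cycles for r in results})
    cmaps = {"smm": "Blues", "two_thirds": "Oranges"}
    import matplotlib.pyplot as plt

    for perf in results:
        xs = [1.0 - p.specificity for p in perf.operating_points]
        ys = [p.sensitivity for p in perf.operating_points]
        shade = 0.35 + 0.6 * (
            (cycle_counts.index(perf.n_cycles) + 1) / max(1, len(cycle_counts))
        )
        color = plt.get_cmap(cmaps[perf.criterion])(min(shade, 1.0))
        label = f"{perf.criterion} {perf.n_cycles}c (AUC={perf.auc:.3f})"
        ax.plot(xs, ys, color=color, label=label)
        if perf.canonical is not None:
            ax.plot(
                1.0 - perf.canonical.specificity,
                perf.canonical.sensitivity,
                "o",
                color=color,
                markersize=4,
            )
    ax.plot([0, 1], [0, 1], "k:", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_alpha_sweep(sweep, path: str | None = None, ax=None):
    """Fraction diagnosed vs alpha, with the null reference line (y = alpha)."""
    ax = _get_axes(ax)
    ax.plot(sweep["alpha"], sweep["frac_smm_positive"], "k-", label="sMM(alpha)")
    ax.plot(
        sweep["alpha"],
        sweep["frac_two_thirds_smm_positive"],
        "b--",
        label="sMM among 2/3-positive",
    )
    ax.plot(sweep["alpha"], sweep["alpha"], "r-", linewidth=0.8, label="null expectation")
    ax.set_xlabel("alpha")
    ax.set_ylabel("fraction diagnosed")
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
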