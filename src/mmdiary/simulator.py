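"""Markov-chain diary simulator with menstrually modulated onset probability.

Each simulated day the subject is either susceptible or in an attack.  From
the susceptible state an attack starts with probability ``mu_M`` on menstrual
window days and ``mu_NM`` elsewhere (equal under the null); an ongoing attack
continues with probability ``delta`` regardless of menstrual state, so attack
durations are geometric with mean ``1/(1-delta)``.

The layout fixes the menstrual calendar: ``n_cycles`` cycles of
``cycle_length_days`` (default 28, laid out as 23 non-window days followed by
the 5 window days) plus a windowless tail (default 10 days into the next
cycle).  Bleeding is recorded on the window's third through fifth days so the
onset day sits at window centre and downstream window detection recovers the
layout exactly.

Randomness is reproducible: each diary consumes one uniform per day from its
own child stream spawned from the population seed, so results do not depend
on batch size or ordering.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .criteria import MarkovParams
from .diary import Diary, WINDOW_HALF_WIDTH

#: study defaults: subgroup means of the clinical cohort (per-day probabilities)
POSITIVE_PARAMS = MarkovParams(mu=0.073, mu_nm=0.045, mu_m=0.244, delta=0.444)
NEGATIVE_PARAMS = MarkovParams.flat(mu=0.083, delta=0.444)


@dataclass(frozen=True)
class DiaryLayout:
    """Menstrual calendar of a simulated diary."""

    n_cycles: int = 4
    cycle_length_days: int = 28
    window_offset: int = 23  # non-window days preceding the 5-day window
    tail_days: int = 10

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.cycle_length_days < 15:
            raise ValueError("cycle length must be at least 15 days")
        if not 2 <= self.window_offset <= self.cycle_length_days - 5:
            raise ValueError(
                "window_offset must leave room for the 5-day window and its onset"
            )
        if self.tail_days < 0:
            raise ValueError("tail_days must be non-negative")

    @property
    def n_days(self) -> int:
        return self.n_cycles * self.cycle_length_days + self.tail_days

    @property
    def onset_days(self) -> np.ndarray:
        """1-based bleeding-onset day of each cycle (window centre)."""
        starts = np.arange(self.n_cycles) * self.cycle_length_days
        return starts + self.window_offset + WINDOW_HALF_WIDTH + 1

    def window_mask(self) -> np.ndarray:
        """0-based boolean mask of window days."""
        mask = np.zeros(self.n_days, dtype=bool)
        for onset in self.onset_days:
            mask[onset - 1 - WINDOW_HALF_WIDTH : onset + WINDOW_HALF_WIDTH] = True
        return mask

    def bleeding_flags(self) -> np.ndarray:
        """0-based boolean mask of bleeding days (onset through onset + 2)."""
        mask = np.zeros(self.n_days, dtype=bool)
        for onset in self.onset_days:
            mask[onset - 1 : onset + WINDOW_HALF_WIDTH] = True
        return mask


@dataclass(frozen=True)
class SimTrace:
    """Ground truth of one simulated diary: true chain episodes."""

    n_onsets: int
    attack_days: int

    @property
    def mean_attack_duration(self) -> float:
        return self.attack_days / self.n_onsets if self.n_onsets else float("nan")


class PointMass:
    """Degenerate parameter distribution: every subject gets ``params``."""

    def __init__(self, params: MarkovParams) -> None:
        self.params = params

    def sample(self, n: int, rng: np.random.Generator) -> MarkovParams | list[MarkovParams]:
        return [self.params] * n


class LogNormalSpread:
    """Multiplicative log-normal spread around base parameters.

    The mu's are scaled by independent log-normal factors with log-sd
    ``sigma`` and clipped to [0, 1]; delta is kept fixed.  Emulates drawing
    subjects from an empirical parameter distribution.
    """

    def __init__(self, params: MarkovParams, sigma: float = 0.25) -> None:
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        self.params = params
        self.sigma = sigma

    def sample(self, n: int, rng: np.random.Generator) -> list[MarkovParams]:
        out = []
        for _ in range(n):
            f_nm, f_m = np.exp(rng.normal(0.0, self.sigma, size=2))
            mu_nm = min(1.0, self.params.mu_nm * f_nm)
            mu_m = min(1.0, self.params.mu_m * f_m)
            out.append(
                MarkovParams(
                    mu=min(1.0, self.params.mu * f_nm),
                    mu_nm=mu_nm,
                    mu_m=mu_m,
                    delta=self.params.delta,
                )
            )
        return out


@dataclass
class PopulationSpec:
    """A labelled two-arm simulated population."""

    n_diaries: int = 10_000
    positive_params: object = field(default_factory=lambda: PointMass(POSITIVE_PARAMS))
    negative_params: object = field(default_factory=lambda: PointMass(NEGATIVE_PARAMS))
    seed: int = 0


@dataclass
class LabelledPopulation:
    """Simulated diaries with ground-truth labels and chain traces."""

    diaries: list[Diary]
    labels: np.ndarray  # True = simulated under the alternative (MM present)
    traces: list[SimTrace]


def _child_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _chain(
    uniforms: np.ndarray, mu_day: np.ndarray, delta: float | np.ndarray
) -> np.ndarray:
    """Run the two-state chain on pre-drawn uniforms.

    ``uniforms`` and the output have shape (n_diaries, n_days); ``mu_day``
    broadcasts to that shape.  One uniform is consumed per diary-day.
    """
    n, T = uniforms.shape
    mu_day = np.broadcast_to(mu_day, (n, T))
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (n,))
    migraine = np.zeros((n, T), dtype=bool)
    in_attack = np.zeros(n, dtype=bool)
    for t in range(T):
        u = uniforms[:, t]
        cont = in_attack & (u < delta)
        onset = ~in_attack & (u < mu_day[:, t])
        in_attack = cont | onset
        migraine[:, t] = in_attack
    return migraine


def simulate_batch(
    params: Sequence[MarkovParams],
    layout: DiaryLayout,
    rngs: Sequence[np.random.Generator],
    prefix: str = "sim",
) -> tuple[list[Diary], list[SimTrace]]:
    """Simulate one diary per parameter set, each from its own stream."""
    n = len(params)
    T = layout.n_days
    uniforms = np.stack([rng.random(T) for rng in rngs])
    win = layout.window_mask()
    mu_day = np.where(
        win[None, :],
        np.array([p.mu_m for p in params])[:, None],
        np.array([p.mu_nm for p in params])[:, None],
    )
    delta = np.array([p.delta for p in params])
    migraine = _chain(uniforms, mu_day, delta)

    # chain episodes are maximal migraine runs: leaving the attack state
    # produces at least one migraine-free day before a new onset is possible
    prev = np.concatenate([np.zeros((n, 1), bool), migraine[:, :-1]], axis=1)
    n_onsets = (migraine & ~prev).sum(axis=1)

    bleeding = layout.bleeding_flags()
    diaries = [
        Diary(f"{prefix}{i:05d}", migraine[i], bleeding) for i in range(n)
    ]
    traces = [
        SimTrace(int(n_onsets[i]), int(migraine[i].sum())) for i in range(n)
    ]
    return diaries, traces


def simulate_diary(
    params: MarkovParams,
    layout: DiaryLayout,
    rng: np.random.Generator,
    subject_id: str = "sim",
    return_trace: bool = False,
):
    """Simulate a single diary (one uniform per day from ``rng``)."""
    diaries, traces = simulate_batch([params], layout, [rng], prefix="")
    diary = Diary(subject_id, diaries[0].migraine, diaries[0].bleeding)
    return (diary, traces[0]) if return_trace else diary


def sample_population(spec: PopulationSpec, layout: DiaryLayout) -> LabelledPopulation:
    """Simulate ``n_diaries`` true positives and ``n_diaries`` true negatives.

    Fully reproducible from ``spec.seed``: parameter draws and per-diary
    streams all derive from it.
    """
    ss = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    pos_params = list(spec.positive_params.sample(spec.n_diaries, param_rng))
    neg_params = list(spec.negative_params.sample(spec.n_diaries, param_rng))
    streams = _child_streams(spec.seed + 1, 2 * spec.n_diaries)
    pos, pos_traces = simulate_batch(
        pos_params, layout, streams[: spec.n_diaries], prefix="pos"
    )
    neg, neg_traces = simulate_batch(
        neg_params, layout, streams[spec.n_diaries :], prefix="neg"
    )
    labels = np.concatenate(
        [np.ones(spec.n_diaries, bool), np.zeros(spec.n_diaries, bool)]
    )
    return LabelledPopulation(pos + neg, labels, pos_traces + neg_traces)
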