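import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmdiary import Diary

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def fig2_diary() -> Diary:
    """The 9-day worked diary excerpt: migraine days 2-4, 8, 9; bleeding onset day 4."""
    return Diary(
        "fig2",
        migraine=[0, 1, 1, 1, 0, 0, 0, 1, 1],
        bleeding=[0, 0, 0, 1, 0, 0, 0, 0, 0],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190906)


def diary_from_onsets(onsets, n_days, migraine=None, subject_id="s") -> Diary:
    """Build a diary with single-day bleeds at the given 1-based onset days."""
    bleeding = np.zeros(n_days, dtype=bool)
    for o in onsets:
        bleeding[o - 1] = True
    mig = np.zeros(n_days, dtype=bool) if migraine is None else np.asarray(migraine, bool)
    return Diary(subject_id, mig, bleeding)


def diary_from_cycle_lengths(lengths, lead=5, tail=5, subject_id="s") -> Diary:
    """Build a diary whose consecutive onset gaps equal ``lengths``."""
    onsets = [lead + 1]
    for L in lengths:
        onsets.append(onsets[-1] + L)
    n_days = onsets[-1] + tail
    return diary_from_onsets(onsets, n_days, subject_id=subject_id)
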