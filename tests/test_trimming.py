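"""Markov-role day classification and the 2x2 contingency counts.

`oracle_states` is an independent, deliberately plain day-by-day re-statement
of the trimming rules used to cross-check the vectorised implementation.
"""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmdiary import (
    ContingencyCounts,
    DayState,
    Diary,
    classify_days,
    detect_windows,
    impute_locked_days,
    segment_attacks,
    trimmed_counts,
    untrimmed_counts,
)

from conftest import diary_from_onsets


def oracle_states(mig: list[bool]) -> list[str]:
    """Brute-force day classification: S, AS, ON, RF, EX per day."""
    n = len(mig)
    runs = []
    i = 0
    while i < n:
        if mig[i]:
            j = i
            while j + 1 < n and mig[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    complexes = []
    for s, e in runs:
        if complexes and s <= complexes[-1][1] + 2:
            complexes[-1][1] = e
        else:
            complexes.append([s, e])
    states = ["S"] * n
    for s, e in complexes:
        identifiable = s != 0
        for d in range(s, e + 1):
            if not mig[d]:
                states[d] = "RF"
            elif not identifiable:
                states[d] = "EX"
            elif d == s:
                states[d] = "AS"
            else:
                states[d] = "ON"
        for d in (e + 1, e + 2):
            if d < n:
                states[d] = "RF"
    return states


_NAMES = {
    DayState.SUSCEPTIBLE: "S",
    DayState.ATTACK_START: "AS",
    DayState.ONGOING: "ON",
    DayState.REFRACTORY: "RF",
    DayState.EXCLUDED: "EX",
}


# -- worked example -----------------------------------------------------------


def test_fig2_attack_segmentation(fig2_diary):
    attacks = segment_attacks(fig2_diary)
    assert [(a.start_day, a.end_day, a.identifiable_start) for a in attacks] == [
        (2, 4, True),
        (8, 9, True),
    ]


def test_fig2_removed_days_are_3_to_6_and_9(fig2_diary):
    states = classify_days(fig2_diary)
    removed = {
        i + 1
        for i in range(fig2_diary.n_days)
        if states[i] not in (DayState.SUSCEPTIBLE, DayState.ATTACK_START)
    }
    assert removed == {3, 4, 5, 6, 9}


def test_fig2_untrimmed_counts(fig2_diary):
    c = untrimmed_counts(fig2_diary, detect_windows(fig2_diary))
    assert (c.N, c.K, c.n, c.k) == (9, 5, 5, 3)


def test_fig2_trimmed_counts(fig2_diary):
    c = trimmed_counts(fig2_diary, detect_windows(fig2_diary))
    assert (c.N, c.K, c.n, c.k) == (4, 1, 2, 1)


# -- boundary rules -----------------------------------------------------------


def test_isolated_attack_gets_two_refractory_days():
    mig = np.zeros(10, bool)
    mig[4] = True  # attack on day 5
    states = classify_days(Diary("x", mig, np.zeros(10, bool)))
    assert states[4] == DayState.ATTACK_START
    assert states[5] == states[6] == DayState.REFRACTORY
    assert all(states[i] == DayState.SUSCEPTIBLE for i in (0, 1, 2, 3, 7, 8, 9))


def test_attack_at_diary_start_is_excluded_with_refractory_tail():
    mig = np.array([1, 1, 0, 0, 0], bool)
    states = classify_days(Diary("x", mig, np.zeros(5, bool)))
    assert states[0] == states[1] == DayState.EXCLUDED
    assert states[2] == states[3] == DayState.REFRACTORY
    assert states[4] == DayState.SUSCEPTIBLE
    (attack,) = segment_attacks(Diary("x", mig, np.zeros(5, bool)))
    assert not attack.identifiable_start


def test_attack_truncated_by_diary_end_still_counts():
    mig = np.array([0, 0, 1, 1], bool)
    d = Diary("x", mig, np.zeros(4, bool))
    (attack,) = segment_attacks(d)
    assert attack.identifiable_start
    states = classify_days(d)
    assert states[2] == DayState.ATTACK_START


def test_migraine_on_refractory_day_merges_into_previous_attack():
    # non-imputed input: runs on days 1-2 and 4 (gap day 3); day 4 is refractory
    mig = np.array([0, 1, 1, 0, 1, 0, 0, 0], bool)
    d = Diary("x", mig, np.zeros(8, bool))
    states = classify_days(d)
    assert states[1] == DayState.ATTACK_START
    assert states[4] == DayState.ONGOING  # merged, not a new start
    assert states[3] == DayState.REFRACTORY  # gap day inside the complex
    assert states[5] == states[6] == DayState.REFRACTORY  # restart after merge
    assert states[7] == DayState.SUSCEPTIBLE


def test_all_clear_diary_is_all_susceptible():
    states = classify_days(Diary("x", np.zeros(6, bool), np.zeros(6, bool)))
    assert (states == DayState.SUSCEPTIBLE).all()


def test_no_classifiable_days_raises():
    d = Diary("x", np.ones(4, bool), np.array([0, 1, 1, 1], bool))
    with pytest.raises(ValueError, match="classifiable"):
        trimmed_counts(d, detect_windows(d))


def test_counts_validate_invariants():
    with pytest.raises(ValueError):
        ContingencyCounts(N=4, K=5, n=2, k=1, variant="trimmed_onsets")
    with pytest.raises(ValueError):
        ContingencyCounts(N=4, K=2, n=2, k=3, variant="trimmed_onsets")


# -- properties against the oracle -------------------------------------------


@given(st.lists(st.booleans(), min_size=1, max_size=120))
def test_classification_matches_brute_force_oracle(mig):
    d, _ = impute_locked_days(Diary("x", mig, [False] * len(mig)))
    states = classify_days(d)
    assert [_NAMES[DayState(s)] for s in states] == oracle_states(list(d.migraine))


@given(st.lists(st.booleans(), min_size=1, max_size=120), st.data())
def test_partition_and_count_invariants(mig, data):
    n_days = len(mig)
    onsets = data.draw(
        st.lists(
            st.integers(1, n_days), unique=True, max_size=max(1, n_days // 20)
        )
    )
    d = diary_from_onsets(sorted(onsets), n_days, migraine=mig)
    d, _ = impute_locked_days(d)
    states = classify_days(d)
    assert len(states) == d.n_days  # every day gets exactly one state
    attacks = segment_attacks(d)
    n_identifiable = sum(a.identifiable_start for a in attacks)
    assert (states == DayState.ATTACK_START).sum() == n_identifiable
    windows = detect_windows(d)
    u = untrimmed_counts(d, windows)
    try:
        t = trimmed_counts(d, windows, states)
    except ValueError:
        return  # diary fully trimmed away
    assert t.N <= u.N
    if u.n == 0:
        assert t.N == u.N
    elif any(
        a.length_days > 1 or a.end_day < d.n_days or not a.identifiable_start
        for a in attacks
    ):
        # any ongoing/excluded day or in-range refractory day shrinks N; the
        # sole exception is a single-day attack on the diary's final day
        assert t.N < u.N
    assert t.n == n_identifiable


def test_length_one_attacks_far_apart_equal_trimmed_and_untrimmed_n():
    mig = np.zeros(20, bool)
    mig[[3, 9, 15]] = True
    d = Diary("x", mig, np.zeros(20, bool))
    windows = detect_windows(d)
    assert untrimmed_counts(d, windows).n == trimmed_counts(d, windows).n == 3
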