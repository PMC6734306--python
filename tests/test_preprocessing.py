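"""Eligibility filters, atypical-cycle handling, truncation, locked-day imputation."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmdiary import (
    Diary,
    cycle_lengths,
    drop_atypical_cycles,
    eligibility,
    impute_locked_days,
    preprocess,
    truncate_diary,
)
from mmdiary.diary import bleeding_onsets

from conftest import diary_from_cycle_lengths, diary_from_onsets


# -- cycle lengths ------------------------------------------------------------


def test_cycle_lengths_between_consecutive_onsets():
    d = diary_from_onsets([10, 38, 66], 80)
    assert [c.length_days for c in cycle_lengths(d)] == [28, 28]


def test_single_onset_has_no_cycles():
    assert cycle_lengths(diary_from_onsets([10], 30)) == []


def test_cycle_lengths_span_wide_range():
    d = diary_from_onsets([5, 20, 104], 120)
    assert [c.length_days for c in cycle_lengths(d)] == [15, 84]


# -- atypical-cycle removal ---------------------------------------------------


def test_atypical_cycle_retains_latter_three_cycles():
    d = diary_from_cycle_lengths([28, 28, 80, 28, 28, 28])
    cycles = cycle_lengths(d)
    kept, report = drop_atypical_cycles(d, cycles)
    assert not report.excluded
    # retained portion starts at the onset opening the valid run
    assert report.retained_day_range[0] == cycles[3].start_onset
    assert [c.length_days for c in cycle_lengths(kept)] == [28, 28, 28]


def test_atypical_cycle_without_three_consecutive_excludes_diary():
    d = diary_from_cycle_lengths([28, 28, 80, 28, 28])
    kept, report = drop_atypical_cycles(d, cycle_lengths(d))
    assert kept is None
    assert report.excluded and report.exclusion_reason == "atypical_unsalvageable"


def test_all_typical_cycles_unchanged():
    d = diary_from_cycle_lengths([28, 28, 28])
    kept, report = drop_atypical_cycles(d, cycle_lengths(d))
    assert kept == d and not report.excluded


def test_longest_valid_run_wins_earliest_on_ties():
    # two disjoint 3-cycle runs around a 200-day gap; equal length -> earliest
    d = diary_from_cycle_lengths([28, 28, 28, 200, 28, 28, 28])
    kept, report = drop_atypical_cycles(d, cycle_lengths(d))
    assert report.retained_day_range[0] == 1  # head run starts at diary start
    assert [c.length_days for c in cycle_lengths(kept)] == [28, 28, 28]


# -- eligibility --------------------------------------------------------------


@pytest.mark.parametrize(
    "lengths,expected",
    [([28, 28], True), ([28, 28, 28], False), ([28] * 15, False)],
)
def test_eligibility_requires_three_consecutive_cycles(lengths, expected):
    report = eligibility(diary_from_cycle_lengths(lengths))
    assert report.excluded is expected
    if expected:
        assert report.exclusion_reason == "too_few_cycles"


# -- truncation ---------------------------------------------------------------


def test_truncation_keeps_15_days_around_bleeding():
    bleeding = np.zeros(100, bool)
    bleeding[[29, 69]] = True  # bleeds on days 30 and 70
    d = Diary("x", np.zeros(100, bool), bleeding)
    t = truncate_diary(d)
    assert t.n_days == 71  # days 15..85 re-anchored
    assert list(bleeding_onsets(t)) == [16, 56]


def test_truncation_no_left_cut_when_bleed_on_day_one():
    d = diary_from_onsets([1], 30)
    assert truncate_diary(d).n_days == 16


def test_truncation_noop_when_diary_within_margins():
    d = diary_from_onsets([10, 20], 30)
    assert truncate_diary(d) == d


def test_truncation_requires_bleeding():
    with pytest.raises(ValueError, match="no bleeding"):
        truncate_diary(Diary("x", [1, 0], [0, 0]))


# -- locked-day imputation ----------------------------------------------------


def test_single_locked_day_imputed():
    d = Diary("x", [0, 1, 0, 1, 0], [0] * 5)
    out, n = impute_locked_days(d)
    assert n == 1 and list(out.migraine) == [False, True, True, True, False]


def test_two_day_gap_not_locked():
    d = Diary("x", [1, 0, 0, 1], [0] * 4)
    out, n = impute_locked_days(d)
    assert n == 0 and out == d


def test_alternating_pattern_fills_fully():
    d = Diary("x", [1, 0, 1, 0, 1], [0] * 5)
    out, n = impute_locked_days(d)
    assert n == 2 and out.migraine.all()


def test_all_migraine_unchanged():
    d = Diary("x", [1, 1, 1], [0, 0, 0])
    out, n = impute_locked_days(d)
    assert n == 0 and out == d


@given(st.lists(st.booleans(), min_size=1, max_size=80))
def test_imputation_monotone_and_fixed_point(mig):
    d = Diary("x", mig, [False] * len(mig))
    out, n = impute_locked_days(d)
    assert out.migraine.sum() == d.migraine.sum() + n
    assert (out.migraine | d.migraine == out.migraine).all()
    again, m = impute_locked_days(out)
    assert m == 0 and again == out


# -- full pipeline ------------------------------------------------------------


def test_pipeline_is_idempotent():
    rng = np.random.default_rng(7)
    onsets = [20, 48, 76, 104, 132]
    d = diary_from_onsets(onsets, 160, migraine=rng.random(160) < 0.2)
    first, report = preprocess(d)
    assert first is not None and not report.excluded
    second, report2 = preprocess(first)
    assert second == first and report2.imputed_locked_days == 0


def test_pipeline_excludes_short_diaries():
    d = diary_from_cycle_lengths([28, 28])
    kept, report = preprocess(d)
    assert kept is None and report.exclusion_reason == "too_few_cycles"


def test_truncation_never_increases_counts():
    rng = np.random.default_rng(3)
    d = diary_from_onsets([40, 70, 100, 130], 200, migraine=rng.random(200) < 0.3)
    t = truncate_diary(d)
    assert t.n_days <= d.n_days
    assert t.migraine.sum() <= d.migraine.sum()
    assert t.bleeding.sum() == d.bleeding.sum()
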