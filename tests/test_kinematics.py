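"""Force-trace kinematics: episodes, trial summaries, completion detection."""

import numpy as np
import pytest

from tablet_vfhp.errors import NoContactError, ValidationError
from tablet_vfhp.kinematics import (
    ForceTrace,
    detect_contact_episodes,
    detect_trial_end,
    force_histogram,
    summarize_trial,
)

DT = 25.0


def make_trace(force, **labels):
    force = np.asarray(force, dtype=float)
    return ForceTrace(times_ms=np.arange(force.size) * DT, force=force, **labels)


def test_single_episode_duration_and_mean_force():
    f = np.zeros(100)
    f[10:50] = 10.0  # 40 consecutive samples
    eps = detect_contact_episodes(make_trace(f))
    assert len(eps) == 1
    assert eps[0].duration_ms == pytest.approx(40 * DT)  # 1.000 s
    assert eps[0].mean_force == pytest.approx(10.0)
    assert eps[0].n_samples == 40


def test_all_zero_trace_has_no_episodes_and_flags_no_contact():
    trace = make_trace(np.zeros(50))
    assert detect_contact_episodes(trace) == []
    s = summarize_trial(trace)
    assert s.no_contact
    assert s.contact_time_s == 0.0 and s.total_writing_time_s == 0.0


def test_runs_separated_by_one_null_sample_are_two_episodes():
    f = np.zeros(30)
    f[5:10] = 4.0
    f[11:15] = 6.0
    eps = detect_contact_episodes(make_trace(f))
    assert len(eps) == 2
    assert eps[0].n_samples == 5 and eps[1].n_samples == 4


def test_summary_matches_direct_arithmetic():
    # first contact at 0.5 s, last lift-off at 3.0 s, 1.0 s total contact
    f = np.zeros(200)
    f[20:40] = 10.0   # 0.5 s contact starting at 500 ms
    f[100:120] = 10.0  # 0.5 s contact starting at 2500 ms, ends 3000 ms
    s = summarize_trial(make_trace(f))
    assert s.contact_time_s == pytest.approx(1.0)
    assert s.total_writing_time_s == pytest.approx(2.5)
    assert s.mean_contact_force == pytest.approx(10.0)
    assert s.n_episodes == 2


def test_single_sample_touch_is_degenerate_but_valid():
    f = np.zeros(10)
    f[4] = 3.0
    s = summarize_trial(make_trace(f))
    assert s.contact_time_s == pytest.approx(0.025)
    assert s.total_writing_time_s == pytest.approx(0.025)


def test_contact_time_is_sample_count_times_interval():
    rng = np.random.default_rng(8)
    f = rng.choice([0.0, 5.0, 12.0], size=400, p=[0.5, 0.3, 0.2])
    s = summarize_trial(make_trace(f))
    assert s.contact_time_s == pytest.approx((f > 0).sum() * DT / 1000.0)


def test_contact_time_is_additive_across_concatenated_episodes():
    f1 = np.zeros(80); f1[10:30] = 5.0
    f2 = np.zeros(80); f2[40:70] = 7.0
    both = np.zeros(160); both[10:30] = 5.0; both[120:150] = 7.0
    c1 = summarize_trial(make_trace(f1)).contact_time_s
    c2 = summarize_trial(make_trace(f2)).contact_time_s
    assert summarize_trial(make_trace(both)).contact_time_s == pytest.approx(c1 + c2)


def test_null_padding_leaves_summary_invariant():
    f = np.zeros(100)
    f[20:60] = 9.0
    padded = np.concatenate([np.zeros(40), f, np.zeros(40)])
    s0 = summarize_trial(make_trace(f))
    s1 = summarize_trial(make_trace(padded))
    assert s1.contact_time_s == s0.contact_time_s
    assert s1.total_writing_time_s == s0.total_writing_time_s
    assert s1.mean_contact_force == s0.mean_contact_force


def test_trial_end_found_at_start_of_terminal_lift():
    f = np.zeros(200)
    f[20:120] = 8.0  # 2 s of trailing zeros after sample 119
    end = detect_trial_end(make_trace(f), lift_duration_ms=1000.0)
    assert end == pytest.approx(120 * DT)


def test_trial_end_falls_back_to_trace_end_without_terminal_lift():
    f = np.zeros(100)
    f[20:] = 8.0
    end = detect_trial_end(make_trace(f), lift_duration_ms=1000.0)
    assert end == pytest.approx(99 * DT)


def test_short_interior_lift_does_not_end_the_trial():
    f = np.zeros(200)
    f[10:50] = 5.0
    # 0.5 s interior gap, then more writing, then a long terminal lift
    f[70:100] = 5.0
    end = detect_trial_end(make_trace(f), lift_duration_ms=1000.0)
    assert end == pytest.approx(100 * DT)


def test_trial_end_requires_some_contact():
    with pytest.raises(NoContactError):
        detect_trial_end(make_trace(np.zeros(50)))


def test_histogram_counts_null_values_and_conserves_samples():
    f = np.concatenate([np.zeros(100), np.full(50, 10.0)])
    counts = force_histogram(make_trace(f), [0.0, 5.0, 15.0, 20.0])
    assert counts.tolist() == [100, 50, 0]
    assert counts.sum() == f.size


def test_above_threshold_contact_definition_is_strict():
    f = np.full(20, 2.0)
    assert detect_contact_episodes(make_trace(f), threshold=2.0) == []


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(times_ms=[0, 25, 25], force=[0, 0, 0]),        # not strictly increasing
        dict(times_ms=[0, 50], force=[0, 0]),               # spacing off-nominal
        dict(times_ms=[0, 25], force=[0, -1]),              # negative force
        dict(times_ms=[], force=[]),                        # empty
    ],
)
def test_invalid_traces_rejected(kwargs):
    with pytest.raises(ValidationError):
        ForceTrace(times_ms=np.asarray(kwargs["times_ms"], dtype=float),
                   force=np.asarray(kwargs["force"], dtype=float))


def test_label_vocabularies_are_closed():
    with pytest.raises(ValidationError):
        make_trace(np.zeros(4), condition="maybe_vfhp")
    with pytest.raises(ValidationError):
        make_trace(np.zeros(4), task="sudoku")
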