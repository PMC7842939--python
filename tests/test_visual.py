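"""Automated visual-identification heuristic and the rater merge."""

import numpy as np
import pytest

from bedrestdt import (
    HeuristicParams,
    LabelSequence,
    State,
    episodes_from_labels,
    merge_raters,
    score_reference,
)
from conftest import flat_series


def brute_force_boundaries(x, p=HeuristicParams()):
    """Independent literal scan of the start/end rules (no minima pass)."""
    n = len(x)
    marks = []  # (index, 'start'|'end-exclusive')
    pos, seeking_start = 0, True
    while pos < n:
        found = None
        if seeking_start:
            for i in range(pos, n):
                run = x[i : min(i + p.start_run_min, n)]
                if all(v <= p.low_threshold for v in run):
                    confirm = x[
                        min(i + p.start_run_min, n) : min(
                            i + p.start_run_min + p.start_confirm_min, n
                        )
                    ]
                    if sum(v > p.low_threshold for v in confirm) <= p.start_confirm_exceptions:
                        found = i
                        break
        else:
            for j in range(pos, n):
                if x[j] >= p.high_threshold:
                    window = x[j + 1 : min(j + 1 + p.end_confirm_window, n)]
                    if sum(v >= p.high_threshold for v in window) >= p.end_confirm_hits:
                        found = j
                        break
        if found is None:
            break
        marks.append((found, "start" if seeking_start else "end"))
        pos, seeking_start = max(found, pos), not seeking_start
    return marks


def test_all_low_trace_is_one_bedrest_episode():
    series = flat_series(np.zeros(480))
    labels = score_reference(series)
    assert (labels.states == int(State.BEDREST)).all()


def test_all_high_trace_is_all_wake():
    series = flat_series(np.full(480, 1000))
    labels = score_reference(series)
    assert (labels.states == int(State.WAKE)).all()


def test_constructed_trace_boundaries_match_brute_force():
    x = np.concatenate([np.full(120, 800), np.full(600, 20), np.full(120, 800)])
    marks = brute_force_boundaries(list(map(float, x)))
    assert marks[0] == (120, "start") and marks[1] == (720, "end")
    labels = score_reference(flat_series(x))
    bed = np.flatnonzero(labels.states == int(State.BEDREST))
    assert bed.min() == 120 and bed.max() == 719  # bedrest-end is minute 719


def test_start_confirm_exceptions_rule():
    # 10 low minutes, then a confirm window with 3 exceptions: start rejected there
    x = np.full(200, 1000.0)
    x[50:60] = 0  # candidate run
    x[60:80] = 0
    x[61] = x[65] = x[70] = 800  # 3 minutes over the low threshold
    labels = score_reference(flat_series(x))
    assert (labels.states[50:60] == int(State.WAKE)).all()
    x[70] = 0  # only 2 exceptions now -> start accepted, but episode must be >= 30 min
    labels = score_reference(flat_series(x))
    assert (labels.states[50:60] == int(State.BEDREST)).any()


def test_end_rule_needs_5_of_9():
    x = np.zeros(300)
    x[200] = 600  # isolated spike: only 0 of next 9 high -> not an end
    labels = score_reference(flat_series(x))
    assert (labels.states == int(State.BEDREST)).all()
    x[201:210] = 600  # now 9 of the next 9 are high; wake run is 10 min
    labels = score_reference(flat_series(x))
    assert (labels.states[:200] == int(State.BEDREST)).all()
    assert (labels.states[200:210] == int(State.WAKE)).all()


def test_short_wake_absorbed_into_bedrest():
    # 100 bedrest + 9 min sustained high + 100 bedrest: the end rule fires,
    # but the resulting interior wake run (< 10 min) is absorbed back.
    x = np.concatenate(
        [np.full(60, 900), np.zeros(100), np.full(9, 900), np.zeros(100), np.full(60, 900)]
    )
    labels = score_reference(flat_series(x))
    bed = [e for e in episodes_from_labels(labels) if e.state == State.BEDREST]
    assert len(bed) == 1 and bed[0].start_index == 60 and bed[0].duration_min >= 200


def test_short_bedrest_demoted_to_wake():
    # a clean 29-min low dip between sustained high activity -> too short
    x = np.full(400, 900.0)
    x[200:229] = 0
    labels = score_reference(flat_series(x))
    assert (labels.states == int(State.WAKE)).all()


def test_minima_invariants_on_random_traces(rng):
    for _ in range(25):
        x = rng.choice([0, 30, 80, 600, 1500], size=600, p=[0.4, 0.1, 0.1, 0.2, 0.2])
        labels = score_reference(flat_series(x))
        eps = episodes_from_labels(labels)
        for k, ep in enumerate(eps):
            if ep.state == State.BEDREST:
                assert ep.duration_min >= 30
            if (
                ep.state == State.WAKE
                and 0 < k < len(eps) - 1
                and eps[k - 1].state == State.BEDREST
                and eps[k + 1].state == State.BEDREST
            ):
                assert ep.duration_min >= 10


def test_determinism(rng):
    x = rng.choice([0, 50, 1000], size=800)
    series = flat_series(x)
    assert score_reference(series) == score_reference(series)


def test_short_series_scores_all_wake_with_warning():
    with pytest.warns(UserWarning):
        labels = score_reference(flat_series(np.zeros(20)))
    assert (labels.states == int(State.WAKE)).all()


def test_merge_raters_rules():
    a = LabelSequence.from_tokens(["bedrest", "bedrest", "wake", "wake"])
    b = LabelSequence.from_tokens(["bedrest", "wake", "bedrest", "wake"])
    true1 = merge_raters(a, b, "True1")
    true2 = merge_raters(a, b, "True2")
    assert true1.to_tokens() == ["bedrest", "wake", "wake", "wake"]
    assert true2.to_tokens() == ["bedrest", "bedrest", "bedrest", "wake"]
    assert merge_raters(a, a, "True1") == a


def test_true2_bedrest_superset_of_true1(rng):
    for _ in range(20):
        a = LabelSequence(rng.choice([0, 1], size=300).astype(np.int8))
        b = LabelSequence(rng.choice([0, 1], size=300).astype(np.int8))
        t1 = merge_raters(a, b, "True1").mask(State.BEDREST)
        t2 = merge_raters(a, b, "True2").mask(State.BEDREST)
        assert (t1 & ~t2).sum() == 0
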