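"""Nap/bedrest-period/awakening classification and daily summaries."""

from datetime import datetime

import numpy as np
import pytest

from bedrestdt import LabelSequence, State, classify_periods, summarize_days
from conftest import flat_series

B, W = int(State.BEDREST), int(State.WAKE)


def labels_of(*runs):
    """Build labels from (state, minutes) runs."""
    parts = [np.full(n, s, dtype=np.int8) for s, n in runs]
    return LabelSequence(np.concatenate(parts))


@pytest.mark.parametrize(
    "minutes,tag",
    [(29, None), (30, "NAP"), (45, "NAP"), (90, "NAP"), (91, "BEDREST_PERIOD"), (600, "BEDREST_PERIOD")],
)
def test_duration_boundaries(minutes, tag):
    labels = labels_of((W, 60), (B, minutes), (W, 60))
    periods, relabeled = classify_periods(labels)
    bedish = [p for p in periods if p.tag in ("NAP", "BEDREST_PERIOD")]
    if tag is None:
        assert bedish == []
        assert (relabeled.states == W).all()  # < 30 min demoted to wake
    else:
        assert len(bedish) == 1 and bedish[0].tag == tag
        assert bedish[0].bedrest_min == minutes


@pytest.mark.parametrize("gap,is_awakening", [(4, False), (5, True), (15, True), (16, False)])
def test_awakening_boundaries(gap, is_awakening):
    labels = labels_of((W, 60), (B, 300), (W, gap), (B, 300), (W, 60))
    periods, _ = classify_periods(labels)
    awakenings = [p for p in periods if p.tag == "AWAKENING"]
    bed_periods = [p for p in periods if p.tag == "BEDREST_PERIOD"]
    if is_awakening:
        assert len(awakenings) == 1 and awakenings[0].duration_min == gap
        assert len(bed_periods) == 1  # flanks merged into one period
        assert bed_periods[0].bedrest_min == 600
    else:
        assert awakenings == []
        assert len(bed_periods) == 2


def test_awakening_inside_long_bedrest_span():
    labels = labels_of((B, 300), (W, 10), (B, 290))
    periods, relabeled = classify_periods(labels)
    assert [p.tag for p in periods] == ["BEDREST_PERIOD", "AWAKENING"]
    # awakening epochs stay wake at the epoch level
    assert (relabeled.states[300:310] == W).all()


def test_short_gap_between_naps_is_not_awakening():
    # merged span 40+10+35 = 85 <= 90: no merge, gap is plain wake
    labels = labels_of((W, 60), (B, 40), (W, 10), (B, 35), (W, 60))
    periods, _ = classify_periods(labels)
    assert [p.tag for p in periods if p.tag != "WAKE"] == ["NAP", "NAP"]


def test_period_minutes_reconcile_with_epoch_bedrest(rng):
    for _ in range(20):
        states = rng.choice([B, W], size=1000, p=[0.4, 0.6]).astype(np.int8)
        labels = LabelSequence(states)
        periods, relabeled = classify_periods(labels)
        period_min = sum(p.bedrest_min for p in periods if p.tag in ("NAP", "BEDREST_PERIOD"))
        assert period_min == int((relabeled.states == B).sum())


def test_classification_depends_only_on_durations():
    a = labels_of((W, 60), (B, 45), (W, 200))
    b = labels_of((W, 200), (B, 45), (W, 60))
    tags_a = [p.tag for p in classify_periods(a)[0] if p.tag != "WAKE"]
    tags_b = [p.tag for p in classify_periods(b)[0] if p.tag != "WAKE"]
    assert tags_a == tags_b == ["NAP"]


def test_daily_summary_passthrough_and_means():
    # day 1: 502 min bedrest overnight block; day 2: one 45-min nap
    runs = [(W, 600), (B, 502), (W, 1440 - 600 - 502)]
    runs += [(W, 700), (B, 45), (W, 1440 - 700 - 45)]
    labels = labels_of(*runs)
    series = flat_series(np.zeros(2880), start=datetime(2022, 3, 7, 0, 0))
    summaries, means = summarize_days(labels, series)
    assert len(summaries) == 2
    assert summaries[0].bedrest_min == 502
    assert summaries[1].nap_count == 1 and summaries[1].nap_min == 45
    assert means["naps_per_day"] == pytest.approx(0.5)
    assert means["bedrest_min_per_day"] == pytest.approx((502 + 45) / 2)


def test_bedrest_crossing_midnight_splits_minutes():
    # 120 min bedrest from 23:00 day 1 to 01:00 day 2
    labels = labels_of((W, 1380), (B, 120), (W, 1380))
    series = flat_series(np.zeros(2880), start=datetime(2022, 3, 7, 0, 0))
    summaries, _ = summarize_days(labels, series)
    assert summaries[0].bedrest_min == 60 and summaries[1].bedrest_min == 60


def test_excluded_epochs_count_nowhere():
    states = np.full(1440, W, dtype=np.int8)
    states[:400] = B
    states[1000:] = int(State.EXCLUDED)
    series = flat_series(np.zeros(1440), start=datetime(2022, 3, 7, 0, 0))
    summaries, _ = summarize_days(LabelSequence(states), series)
    assert summaries[0].bedrest_min + summaries[0].wake_min == 1000
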