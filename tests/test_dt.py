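"""Decision-tree detector: steps 1-4, fallbacks, properties."""

import numpy as np
import pytest

from bedrestdt import (
    DTParams,
    LabelSequence,
    State,
    detect_bedrest,
    episodes_from_labels,
    find_bedrest_end,
    find_bedrest_start,
    initial_status,
    partition_blocks,
)
from conftest import flat_series


def test_partition_blocks_counts_and_tail():
    assert len(partition_blocks(np.zeros(72), 36)) == 2
    means = partition_blocks(np.r_[np.zeros(72), np.full(8, 90.0)], 36)
    assert len(means) == 3
    assert means[2] == pytest.approx(90.0)  # tail averaged over its 8 epochs
    assert partition_blocks(np.full(36, 230.0), 36)[0] == pytest.approx(230.0)


@pytest.mark.parametrize(
    "mean,expected", [(0, State.BEDREST), (1000, State.WAKE), (230, State.BEDREST)]
)
def test_initial_status_tie_goes_to_bedrest(mean, expected):
    assert initial_status(mean, 230.0) == expected


def test_bedrest_start_after_last_trigger_pair():
    x = np.r_[np.full(36, 1000.0), np.zeros(36)]
    means = partition_blocks(x, 36)
    assert find_bedrest_start(x, means, 0, DTParams()) == 36


def test_bedrest_start_fallback_at_block_start():
    # wake status forced, but no epoch ever exceeds the start trigger
    x = np.r_[np.full(36, 250.0), np.zeros(36)]  # block0 mean 250 > 230 -> WAKE
    means = partition_blocks(x, 36)
    assert find_bedrest_start(x, means, 0, DTParams()) == 36  # fallback: block 1 start


def test_no_further_bedrest_when_no_low_block():
    x = np.full(144, 2000.0)
    means = partition_blocks(x, 36)
    assert find_bedrest_start(x, means, 0, DTParams()) is None


def test_bedrest_end_before_first_trigger_pair():
    x = np.r_[np.zeros(400), np.full(72, 2000.0)]
    means = partition_blocks(x, 36)
    assert find_bedrest_end(x, means, 0, DTParams()) == 400  # bedrest-end epoch 399


def test_bedrest_to_end_when_no_high_block():
    x = np.zeros(144)
    means = partition_blocks(x, 36)
    assert find_bedrest_end(x, means, 0, DTParams()) is None


def test_trigger_pair_straddling_block_boundary_is_found():
    # pair at epochs 35,36 straddles blocks 0/1; block 1 is the identified
    # high block and the preceding block is searched jointly
    x = np.zeros(108)
    x[35] = x[36] = 2000.0
    x[37:72] = 500.0  # lifts block 1 mean over the threshold
    means = partition_blocks(x, 36)
    assert find_bedrest_end(x, means, 0, DTParams()) == 35


def test_all_zero_series_single_bedrest_episode():
    labels, episodes = detect_bedrest(flat_series(np.zeros(600)))
    assert (labels.states == int(State.BEDREST)).all()
    assert len(episodes) == 1


def test_all_high_series_all_wake():
    labels, episodes = detect_bedrest(flat_series(np.full(600, 2000)))
    assert (labels.states == int(State.WAKE)).all()


def test_step4_demotes_short_dip():
    # 29-min zero dip at the tail of block 2 inside 1150-count activity:
    # block mean 224 < 230, so the dip is found, but it is < 30 min
    x = np.full(180, 1150.0)
    x[79:108] = 0
    labels, _ = detect_bedrest(flat_series(x))
    assert (labels.states == int(State.WAKE)).all()
    # a 31-min dip in the same position survives step 4
    x = np.full(180, 1150.0)
    x[77:108] = 0
    labels, _ = detect_bedrest(flat_series(x))
    assert (labels.states[77:108] == int(State.BEDREST)).all()


def test_every_worn_epoch_labeled_and_episodes_tile(rng):
    for _ in range(20):
        x = rng.choice([0, 40, 300, 1500], size=500)
        nw = LabelSequence.filled(500, State.WAKE)
        nw.states[200:320] = int(State.NONWEAR)
        labels, episodes = detect_bedrest(flat_series(x), nonwear=nw)
        assert set(np.unique(labels.states[nw.worn])) <= {0, 1}
        assert (labels.states[200:320] == int(State.NONWEAR)).all()
        assert episodes[0].start_index == 0 and episodes[-1].end_index == 500
        for a, b in zip(episodes, episodes[1:]):
            assert a.end_index == b.start_index


def test_no_short_bedrest_episode_survives(rng):
    for _ in range(20):
        x = rng.choice([0, 100, 400, 2000], size=800)
        labels, episodes = detect_bedrest(flat_series(x), DTParams(min_bedrest_min=30))
        for ep in episodes:
            if ep.state == State.BEDREST:
                assert ep.duration_min >= 30


def test_blocks_never_span_nonwear():
    # identical worn data should get identical labels whether or not an
    # unrelated nonwear run precedes it
    x_seg = np.r_[np.full(60, 1500.0), np.zeros(120), np.full(60, 1500.0)]
    lab_alone, _ = detect_bedrest(flat_series(x_seg))
    x_full = np.r_[np.zeros(100), x_seg]
    nw = LabelSequence.filled(len(x_full), State.WAKE)
    nw.states[:100] = int(State.NONWEAR)
    lab_with, _ = detect_bedrest(flat_series(x_full), nonwear=nw)
    assert np.array_equal(lab_with.states[100:], lab_alone.states)


def test_raising_end_trigger_never_ends_bedrest_earlier():
    # night with a brief burst; higher end triggers ignore weaker bursts
    x = np.zeros(600)
    x[100:130] = 700.0  # burst inside bedrest, strong enough to lift a block
    x[400:600] = 2000.0  # true morning rise
    last_end = -1
    for trigger in (500.0, 800.0, 1500.0):
        labels, _ = detect_bedrest(flat_series(x), DTParams(bedrest_end_trigger=trigger))
        bed = np.flatnonzero(labels.states == int(State.BEDREST))
        first_episode_end = int(bed[np.r_[np.diff(bed) > 1, True]][0])
        assert first_episode_end >= last_end
        last_end = first_episode_end


def test_parameters_are_honored():
    # a trace whose activity sits between the preschool and a coarser
    # parameterization: the two must disagree somewhere
    x = np.r_[np.full(72, 700.0), np.zeros(144), np.full(72, 700.0)]
    preschool, _ = detect_bedrest(flat_series(x), DTParams())
    coarse, _ = detect_bedrest(
        flat_series(x),
        DTParams(block_length=60, threshold=800.0, bedrest_start_trigger=1000.0,
                 bedrest_end_trigger=2500.0),
    )
    assert not np.array_equal(preschool.states, coarse.states)


def test_degenerate_trigger_ordering_terminates():
    # end trigger far below the start trigger must still terminate
    x = np.r_[np.full(50, 400.0), np.zeros(100), np.full(50, 400.0)]
    labels, _ = detect_bedrest(
        flat_series(x),
        DTParams(block_length=10, threshold=200.0, bedrest_start_trigger=900.0,
                 bedrest_end_trigger=10.0, min_bedrest_min=0),
    )
    assert len(labels) == len(x)
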