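"""Automated reference scorer mirroring the raters' visual heuristic.

Scanning forward through 60-s epochs of vector-magnitude counts:

* **bedrest-start** — the first minute of ``start_run_min`` (10) consecutive
  minutes <= ``low_threshold`` (100 counts/min) whose following
  ``start_confirm_min`` (20) minutes contain at most
  ``start_confirm_exceptions`` (2) minutes above the low threshold.
* **bedrest-end** — the minute preceding the first minute >=
  ``high_threshold`` (500 counts/min) that is followed by at least
  ``end_confirm_hits`` (5) of the next ``end_confirm_window`` (9) minutes
  >= the high threshold.

After the scan, wake runs shorter than ``min_wake_episode_min`` lying
strictly between bedrest runs are absorbed into bedrest, and then bedrest
runs shorter than ``min_bedrest_episode_min`` are demoted to wake (the
order matters and is fixed: raters perceive consolidated blocks first).
Confirm windows that extend past the end of the recording apply to the
minutes that exist, so trailing bedrest is not discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    AlignmentError,
    ConfigurationError,
    EpochSeries,
    LabelSequence,
    State,
    episodes_from_labels,
)
from .segments import worn_segments

__all__ = ["HeuristicParams", "score_reference", "merge_raters", "enforce_episode_minima"]


@dataclass(frozen=True)
class HeuristicParams:
    low_threshold: float = 100.0
    start_run_min: int = 10
    start_confirm_min: int = 20
    start_confirm_exceptions: int = 2
    high_threshold: float = 500.0
    end_confirm_window: int = 9
    end_confirm_hits: int = 5
    min_bedrest_episode_min: int = 30
    min_wake_episode_min: int = 10

    def __post_init__(self) -> None:
        if min(
            self.start_run_min,
            self.start_confirm_min,
            self.end_confirm_window,
            self.end_confirm_hits,
            self.min_bedrest_episode_min,
            self.min_wake_episode_min,
        ) <= 0 or self.low_threshold < 0 or self.high_threshold < 0:
            raise ConfigurationError("heuristic parameters must be positive")
        if self.end_confirm_hits > self.end_confirm_window:
            raise ConfigurationError("end_confirm_hits cannot exceed end_confirm_window")


def _find_bedrest_start(x: np.ndarray, pos: int, p: HeuristicParams) -> int | None:
    """First index >= pos satisfying the start rule, else None."""
    n = len(x)
    low = x <= p.low_threshold
    for i in range(pos, n):
        run_end = min(i + p.start_run_min, n)
        if not low[i:run_end].all():
            continue
        confirm_end = min(run_end + p.start_confirm_min, n)
        exceptions = int((~low[run_end:confirm_end]).sum())
        if exceptions <= p.start_confirm_exceptions:
            return i
    return None


def _find_bedrest_end(x: np.ndarray, pos: int, p: HeuristicParams) -> int | None:
    """First wake index (the minute after bedrest-end) at >= pos, else None."""
    n = len(x)
    high = x >= p.high_threshold
    for j in range(pos, n):
        if not high[j]:
            continue
        window_end = min(j + 1 + p.end_confirm_window, n)
        if int(high[j + 1 : window_end].sum()) >= p.end_confirm_hits:
            return j
    return None


def enforce_episode_minima(
    labels: LabelSequence, min_bedrest_min: int, min_wake_min: int, epoch_length: int = 60
) -> LabelSequence:
    """Absorb short interior wake into bedrest, then demote short bedrest to wake."""
    out = labels.copy()
    episodes = episodes_from_labels(out, epoch_length)
    for k, ep in enumerate(episodes):
        if (
            ep.state == State.WAKE
            and ep.duration_min < min_wake_min
            and 0 < k < len(episodes) - 1
            and episodes[k - 1].state == State.BEDREST
            and episodes[k + 1].state == State.BEDREST
        ):
            out.states[ep.start_index : ep.end_index] = int(State.BEDREST)
    for ep in episodes_from_labels(out, epoch_length):
        if ep.state == State.BEDREST and ep.duration_min < min_bedrest_min:
            out.states[ep.start_index : ep.end_index] = int(State.WAKE)
    return out


def score_reference(
    series: EpochSeries,
    params: HeuristicParams = HeuristicParams(),
    nonwear: LabelSequence | None = None,
    signal: str = "vm",
) -> LabelSequence:
    """Score a recording with the visual-identification heuristic.

    Non-wear/excluded epochs from ``nonwear`` are preserved and each worn
    segment is scanned independently.
    """
    if series.epoch_length != 60:
        raise ConfigurationError("the heuristic scorer is defined on 60-s epochs")
    if nonwear is not None and len(nonwear) != len(series):
        raise AlignmentError("nonwear labels must align with the series")
    x_all = series.signal(signal)
    out = (
        nonwear.copy() if nonwear is not None else LabelSequence.filled(len(series), State.WAKE)
    )
    for seg_lo, seg_hi in worn_segments(out):
        x = x_all[seg_lo:seg_hi]
        if len(x) < params.start_run_min + params.start_confirm_min:
            warnings.warn(
                f"segment of {len(x)} epochs is shorter than the start rule; scored all wake",
                stacklevel=2,
            )
            out.states[seg_lo:seg_hi] = int(State.WAKE)
            continue
        seg = np.full(len(x), int(State.WAKE), dtype=np.int8)
        pos, seeking_start = 0, True
        while pos < len(x):
            if seeking_start:
                s = _find_bedrest_start(x, pos, params)
                if s is None:
                    break  # wake to end of segment
                pos, seeking_start = s, False
            else:
                j = _find_bedrest_end(x, pos, params)
                if j is None:
                    seg[pos:] = int(State.BEDREST)
                    break
                j = max(j, pos)  # bedrest-end cannot precede bedrest-start
                seg[pos:j] = int(State.BEDREST)
                pos, seeking_start = j, True
        fixed = enforce_episode_minima(
            LabelSequence(seg),
            params.min_bedrest_episode_min,
            params.min_wake_episode_min,
            series.epoch_length,
        )
        out.states[seg_lo:seg_hi] = fixed.states
    return out


def merge_raters(a: LabelSequence, b: LabelSequence, mode: str = "True1") -> LabelSequence:
    """Resolve two raters' scorings into one sequence.

    Disagreements become WAKE under ``True1`` (conservative on bedrest) and
    BEDREST under ``True2``.  Non-wear/excluded epochs must agree.
    """
    if len(a) != len(b):
        raise AlignmentError("rater sequences must have equal length")
    if mode not in ("True1", "True2"):
        raise ValueError(f"mode must be 'True1' or 'True2', got {mode!r}")
    if not np.array_equal(a.worn, b.worn):
        raise AlignmentError("raters disagree on non-wear/excluded epochs")
    out = a.copy()
    disagree = a.worn & (a.states != b.states)
    out.states[disagree] = int(State.WAKE if mode == "True1" else State.BEDREST)
    return out
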