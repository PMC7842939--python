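"""Sadeh actigraphic sleep/wake scoring used as an epoch-level comparator.

Each 60-s epoch is scored with the published linear discriminant

    PS = 7.601 - 0.065*AVG - 1.08*NAT - 0.056*SD - 0.703*LG

where, after capping counts at ``count_cap`` (300):

* ``AVG`` — mean of the centered 11-epoch window (current +/- 5),
* ``NAT`` — number of epochs in that window with counts in the
  [``nat_low``, ``nat_high``) band (default [50, 100)),
* ``SD``  — standard deviation of the trailing 6 epochs (current and the
  previous 5),
* ``LG``  — natural log of (current count + 1).

PS >= 0 scores the epoch as sleep.  Sleep epochs are encoded with the
BEDREST state so the comparator plugs directly into the agreement metrics.
The vertical axis (axis1) is the default input, the form having been
derived for single-axis devices; a vm mode exists for exploratory parity
checks only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AlignmentError, ConfigurationError, EpochSeries, LabelSequence, State
from .segments import worn_segments

__all__ = ["SadehParams", "sadeh_score", "sadeh_statistic"]


@dataclass(frozen=True)
class SadehParams:
    window_half_width: int = 5
    count_cap: float = 300.0
    nat_low: float = 50.0
    nat_high: float = 100.0
    intercept: float = 7.601
    w_mean: float = -0.065
    w_nat: float = -1.08
    w_sd: float = -0.056
    w_log: float = -0.703
    edge_policy: str = "truncate"  # or "zeropad"

    def __post_init__(self) -> None:
        if self.window_half_width < 1:
            raise ConfigurationError("window_half_width must be >= 1")
        if self.nat_low >= self.nat_high:
            raise ConfigurationError("nat_low must be below nat_high")
        if self.edge_policy not in ("truncate", "zeropad"):
            raise ConfigurationError("edge_policy must be 'truncate' or 'zeropad'")


def _window_stats(c: np.ndarray, p: SadehParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AVG, NAT and trailing SD per epoch under the configured edge policy."""
    n = len(c)
    hw = p.window_half_width
    trailing = hw + 1  # current epoch plus the previous hw
    if p.edge_policy == "zeropad":
        padded = np.concatenate((np.zeros(hw), c, np.zeros(hw)))
        win = np.lib.stride_tricks.sliding_window_view(padded, 2 * hw + 1)
        avg = win.mean(axis=1)
        nat = ((win >= p.nat_low) & (win < p.nat_high)).sum(axis=1).astype(float)
        tpad = np.concatenate((np.zeros(trailing - 1), c))
        twin = np.lib.stride_tricks.sliding_window_view(tpad, trailing)
        sd = twin.std(axis=1)
        return avg, nat, sd
    avg = np.empty(n)
    nat = np.empty(n)
    sd = np.empty(n)
    in_band = (c >= p.nat_low) & (c < p.nat_high)
    for i in range(n):
        lo, hi = max(0, i - hw), min(n, i + hw + 1)
        avg[i] = c[lo:hi].mean()
        nat[i] = in_band[lo:hi].sum()
        tlo = max(0, i - trailing + 1)
        sd[i] = c[tlo : i + 1].std()
    return avg, nat, sd


def sadeh_statistic(counts: np.ndarray, params: SadehParams = SadehParams()) -> np.ndarray:
    """Per-epoch sleep score PS; >= 0 means sleep."""
    c = np.minimum(np.asarray(counts, dtype=float), params.count_cap)
    avg, nat, sd = _window_stats(c, params)
    return (
        params.intercept
        + params.w_mean * avg
        + params.w_nat * nat
        + params.w_sd * sd
        + params.w_log * np.log(c + 1.0)
    )


def sadeh_score(
    series: EpochSeries,
    params: SadehParams = SadehParams(),
    nonwear: LabelSequence | None = None,
    signal: str = "axis1",
) -> LabelSequence:
    """Score each worn epoch sleep (BEDREST) or WAKE with the Sadeh discriminant."""
    if series.epoch_length != 60:
        raise ConfigurationError("Sadeh scoring is defined on 60-s epochs")
    if nonwear is not None and len(nonwear) != len(series):
        raise AlignmentError("nonwear labels must align with the series")
    x_all = series.signal(signal)
    out = (
        nonwear.copy() if nonwear is not None else LabelSequence.filled(len(series), State.WAKE)
    )
    for lo, hi in worn_segments(out):
        ps = sadeh_statistic(x_all[lo:hi], params)
        seg = np.where(ps >= 0, int(State.BEDREST), int(State.WAKE)).astype(np.int8)
        out.states[lo:hi] = seg
    return out
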