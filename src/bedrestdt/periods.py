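"""Period-level classification of labeled output and daily summaries.

Bedrest episodes are classified by duration: < 30 min is demoted to wake,
30-90 min is a nap, > 90 min a bedrest period.  Brief wake interruptions
of 5-15 min inside a long bedrest span are awakenings: their epochs stay
WAKE for epoch-level metrics, but at the period level the flanking bedrest
spans are reported as one bedrest period.  Whether a merged span counts as
"long" (> 90 min) is evaluated on the merged span itself (bedrest plus the
candidate awakenings).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .model import EpochSeries, LabelSequence, State, episodes_from_labels

__all__ = ["Period", "DailySummary", "classify_periods", "summarize_days"]

NAP_MIN = 30  # minutes; bedrest below this is wake
NAP_MAX = 90  # minutes; bedrest above this is a full bedrest period
AWAKENING_MIN = 5
AWAKENING_MAX = 15


@dataclass(frozen=True)
class Period:
    """A tagged period over half-open epoch indices.

    ``bedrest_min`` counts only BEDREST epochs inside the span, so period
    totals reconcile exactly with epoch-level bedrest time even when a
    bedrest period spans awakenings.
    """

    tag: str  # WAKE | NAP | BEDREST_PERIOD | AWAKENING
    start_index: int
    end_index: int
    duration_min: float
    bedrest_min: float


@dataclass(frozen=True)
class DailySummary:
    date: date
    bedrest_min: float
    wake_min: float
    nap_count: int
    nap_min: float
    awakening_count: int
    awakening_min: float


def classify_periods(
    labels: LabelSequence, epoch_length: int = 60
) -> tuple[list[Period], LabelSequence]:
    """Tag episodes as naps, bedrest periods and awakenings.

    Returns the tagged periods and the updated epoch labels (bedrest
    episodes shorter than 30 min relabeled WAKE).
    """
    out = labels.copy()
    e2m = epoch_length / 60.0
    for ep in episodes_from_labels(out, epoch_length):
        if ep.state == State.BEDREST and ep.duration_min < NAP_MIN:
            out.states[ep.start_index : ep.end_index] = int(State.WAKE)

    episodes = episodes_from_labels(out, epoch_length)
    periods: list[Period] = []
    i = 0
    while i < len(episodes):
        ep = episodes[i]
        if ep.state != State.BEDREST:
            if ep.state == State.WAKE:
                periods.append(
                    Period("WAKE", ep.start_index, ep.end_index, ep.duration_min, 0.0)
                )
            i += 1
            continue
        # Chain bedrest episodes joined by candidate awakenings (5-15 min wake).
        chain = [i]
        j = i
        while (
            j + 2 < len(episodes)
            and episodes[j + 1].state == State.WAKE
            and AWAKENING_MIN <= episodes[j + 1].duration_min <= AWAKENING_MAX
            and episodes[j + 2].state == State.BEDREST
        ):
            j += 2
            chain.append(j)
        span_start = episodes[chain[0]].start_index
        span_end = episodes[chain[-1]].end_index
        span_min = (span_end - span_start) * e2m
        bedrest_min = sum(episodes[k].duration_min for k in chain)
        if len(chain) > 1 and span_min > NAP_MAX:
            periods.append(
                Period("BEDREST_PERIOD", span_start, span_end, span_min, bedrest_min)
            )
            for k in chain[:-1]:
                gap = episodes[k + 1]
                periods.append(
                    Period(
                        "AWAKENING",
                        gap.start_index,
                        gap.end_index,
                        gap.duration_min,
                        0.0,
                    )
                )
            i = chain[-1] + 1
        else:
            tag = "BEDREST_PERIOD" if ep.duration_min > NAP_MAX else "NAP"
            periods.append(
                Period(tag, ep.start_index, ep.end_index, ep.duration_min, ep.duration_min)
            )
            i += 1
    return periods, out


def summarize_days(
    labels: LabelSequence, series: EpochSeries
) -> tuple[list[DailySummary], dict]:
    """Per-calendar-day minutes over worn epochs, plus means across days.

    A bedrest period crossing midnight contributes its minutes to each day
    it covers; nap and awakening *counts* are assigned to the day the
    episode starts.
    """
    periods, out = classify_periods(labels, series.epoch_length)
    e2m = series.epoch_length / 60.0
    dates = np.array([ts.date() for ts in series.timestamps])
    days = sorted(set(dates))
    day_index = {d: k for k, d in enumerate(days)}

    bedrest = np.zeros(len(days))
    wake = np.zeros(len(days))
    nap_min = np.zeros(len(days))
    awk_min = np.zeros(len(days))
    nap_count = np.zeros(len(days), dtype=int)
    awk_count = np.zeros(len(days), dtype=int)

    for d in days:
        in_day = dates == d
        k = day_index[d]
        bedrest[k] = (in_day & out.mask(State.BEDREST)).sum() * e2m
        wake[k] = (in_day & out.mask(State.WAKE)).sum() * e2m

    bed_mask = out.mask(State.BEDREST)
    for p in periods:
        start_day = day_index[dates[p.start_index]]
        if p.tag == "NAP":
            nap_count[start_day] += 1
        elif p.tag == "AWAKENING":
            awk_count[start_day] += 1
            for idx in range(p.start_index, p.end_index):
                awk_min[day_index[dates[idx]]] += e2m
        if p.tag == "NAP":
            for idx in range(p.start_index, p.end_index):
                if bed_mask[idx]:
                    nap_min[day_index[dates[idx]]] += e2m

    summaries = [
        DailySummary(
            date=d,
            bedrest_min=float(bedrest[k]),
            wake_min=float(wake[k]),
            nap_count=int(nap_count[k]),
            nap_min=float(nap_min[k]),
            awakening_count=int(awk_count[k]),
            awakening_min=float(awk_min[k]),
        )
        for k, d in enumerate(days)
    ]
    means = {
        "bedrest_min_per_day": float(bedrest.mean()),
        "wake_min_per_day": float(wake.mean()),
        "naps_per_day": float(nap_count.mean()),
        "nap_min_per_day": float(nap_min.mean()),
        "awakenings_per_day": float(awk_count.mean()),
        "awakening_min_per_day": float(awk_min.mean()),
    }
    return summaries, means


def summaries_to_frame(summaries: list[DailySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
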