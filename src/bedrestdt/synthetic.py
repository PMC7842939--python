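"""Seeded generator of multi-day minute-epoch traces with ground truth.

The generator emulates the diurnal structure of preschool actigraphy: one
long nighttime bedrest window per day (bedtime around 20:45, roughly 9.5 h
in bed), optional 30-90 min daytime naps, brief 5-15 min awakenings inside
the night, high right-skewed daytime wake counts, low zero-inflated
bedrest counts with occasional movement bursts, and inserted non-wear runs
of exact zeros.  Count regimes deliberately straddle every decision
boundary the scorers use (100 and 500 counts/min for the visual heuristic;
230/305/1129 for the decision tree): wake vm has median ~1500 counts/min,
bedrest epochs are ~80% zeros with residual counts on [1, 100] plus rare
bursts up to ~600.

Each target vm is decomposed onto three axes along a random direction in
the positive octant; axes are rounded to integers and the stored vm is
recomputed from the rounded axes, so the axis/vm invariant is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .io import write_labeled_csv, write_plain_csv
from .model import (
    EpochSeries,
    Episode,
    LabelSequence,
    State,
    ValidationError,
    episodes_from_labels,
)

__all__ = ["SimProfile", "generate", "make_fixture_suite", "series_from_vm"]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class SimProfile:
    """Study-condition defaults for a simulated preschool recording."""

    n_days: int = 7
    start_time: datetime = datetime(2022, 3, 7, 0, 0)  # a Monday
    night_start_mean: float = 1245.0  # clock minutes (20:45)
    night_start_sd: float = 30.0
    night_duration_mean: float = 570.0  # minutes in bed overnight
    night_duration_sd: float = 40.0
    nap_probability: float = 0.3  # per day
    nap_duration_range: tuple[int, int] = (30, 90)
    awakening_rate: float = 0.18  # per bedrest-hour
    awakening_duration_range: tuple[int, int] = (5, 15)
    wake_vm_median: float = 1500.0  # lognormal location (counts/min)
    wake_vm_sigma: float = 0.6
    bedrest_zero_fraction: float = 0.8
    bedrest_low_max: float = 100.0
    burst_rate: float = 0.01  # per bedrest-minute
    burst_range: tuple[float, float] = (200.0, 600.0)
    nonwear_runs: tuple[tuple[int, int], ...] = ((780, 120),)  # 13:00-15:00, day 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if not (0 <= self.nap_probability <= 1):
            raise ValidationError("nap_probability must lie in [0, 1]")
        for lo, hi in (self.nap_duration_range, self.awakening_duration_range):
            if lo <= 0 or lo > hi:
                raise ValidationError("duration ranges must be positive and ordered")
        for start, dur in self.nonwear_runs:
            if dur < 90:
                raise ValidationError("non-wear runs must last >= 90 min to be detectable")
            if start < 0 or start + dur > self.n_days * MINUTES_PER_DAY:
                raise ValidationError("non-wear run outside the recording")


def _sample_nights(profile: SimProfile, rng: np.random.Generator) -> list[tuple[int, int]]:
    nights = []
    total = profile.n_days * MINUTES_PER_DAY
    prev_end = 0
    for d in range(profile.n_days):
        start = int(
            round(d * MINUTES_PER_DAY + rng.normal(profile.night_start_mean, profile.night_start_sd))
        )
        duration = int(
            round(np.clip(rng.normal(profile.night_duration_mean, profile.night_duration_sd), 420, 720))
        )
        start = max(start, prev_end + 60)
        end = min(start + duration, total)
        if end - start >= 120:
            nights.append((start, end))
            prev_end = end
    return nights


def generate(profile: SimProfile) -> tuple[EpochSeries, LabelSequence, list[Episode]]:
    """Simulate one recording; returns the series, truth labels and episodes."""
    rng = np.random.default_rng(profile.seed)
    n = profile.n_days * MINUTES_PER_DAY
    states = np.full(n, int(State.WAKE), dtype=np.int8)

    nights = _sample_nights(profile, rng)
    for start, end in nights:
        states[start:end] = int(State.BEDREST)
        for s, d in profile.nonwear_runs:
            if s < end and s + d > start:
                raise ValidationError(
                    f"non-wear run at minute {s} overlaps the night window [{start}, {end})"
                )

    # Awakenings strictly inside nights (>= 20 min from either edge).
    for start, end in nights:
        hours = (end - start) / 60.0
        for _ in range(rng.poisson(profile.awakening_rate * hours)):
            dur = int(rng.integers(*profile.awakening_duration_range, endpoint=True))
            lo, hi = start + 20, end - 20 - dur
            if hi <= lo:
                continue
            at = int(rng.integers(lo, hi))
            if (states[at - 1 : at + dur + 1] == int(State.BEDREST)).all():
                states[at : at + dur] = int(State.WAKE)

    # Daytime naps: placed in wake time between 09:00 and 18:00, clear of
    # nights and non-wear by a 30-min margin.
    for d in range(profile.n_days):
        if rng.random() >= profile.nap_probability:
            continue
        dur = int(rng.integers(*profile.nap_duration_range, endpoint=True))
        for _ in range(20):  # rejection sampling
            at = int(rng.integers(d * MINUTES_PER_DAY + 540, d * MINUTES_PER_DAY + 1080 - dur))
            window = states[max(at - 30, 0) : at + dur + 30]
            if (window == int(State.WAKE)).all() and not any(
                s < at + dur + 30 and s + du > at - 30 for s, du in profile.nonwear_runs
            ):
                states[at : at + dur] = int(State.BEDREST)
                break

    for s, d in profile.nonwear_runs:
        states[s : s + d] = int(State.NONWEAR)

    # Counts per state.
    vm = np.zeros(n)
    wake_mask = states == int(State.WAKE)
    vm[wake_mask] = rng.lognormal(np.log(profile.wake_vm_median), profile.wake_vm_sigma, wake_mask.sum())
    bed_mask = states == int(State.BEDREST)
    n_bed = int(bed_mask.sum())
    if n_bed:
        low = np.where(
            rng.random(n_bed) < profile.bedrest_zero_fraction,
            0.0,
            rng.uniform(1.0, profile.bedrest_low_max, n_bed),
        )
        burst = rng.random(n_bed) < profile.burst_rate
        low[burst] = rng.uniform(*profile.burst_range, int(burst.sum()))
        vm[bed_mask] = low

    series = series_from_vm(vm, profile.start_time, rng)
    labels = LabelSequence(states)
    return series, labels, episodes_from_labels(labels, 60)


def series_from_vm(
    vm_target: np.ndarray, start_time: datetime, rng: np.random.Generator
) -> EpochSeries:
    """Decompose target vm values onto integer axes (positive octant)."""
    n = len(vm_target)
    direction = np.abs(rng.normal(size=(n, 3)))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    axes = np.round(direction * np.asarray(vm_target, dtype=float)[:, None]).astype(np.int64)
    # A positive target must not round to the zero vector: put it on axis1.
    lost = (np.asarray(vm_target) > 0) & (axes.sum(axis=1) == 0)
    axes[lost, 0] = 1
    return EpochSeries(
        start_time=start_time,
        axis1=axes[:, 0],
        axis2=axes[:, 1],
        axis3=axes[:, 2],
        epoch_length=60,
    )


def _flat_series(vm: np.ndarray, start: datetime) -> EpochSeries:
    counts = np.asarray(np.round(vm), dtype=np.int64)
    return EpochSeries(
        start_time=start,
        axis1=counts,
        axis2=np.zeros_like(counts),
        axis3=np.zeros_like(counts),
        epoch_length=60,
    )


def make_fixture_suite(out_dir) -> list[Path]:
    """Write the canonical small labeled fixtures used by the tests.

    The suite covers: an all-zero day, an all-active day, bedrest episodes
    of 29/30/90/91 min at the nap classification boundaries, wake gaps of
    4/5/15/16 min at the awakening boundaries, and the non-wear
    spike-tolerance cases (90 zeros; 89 zeros; 45 zeros + 1 spike + 45
    zeros).  Every fixture round-trips through the CSV readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    start = datetime(2022, 3, 7, 0, 0)
    written: list[Path] = []

    def emit(name: str, vm: np.ndarray, states: np.ndarray) -> None:
        series = _flat_series(vm, start)
        labels = LabelSequence(states.astype(np.int8))
        path = out_dir / f"{name}.csv"
        write_labeled_csv(series, labels, path)
        written.append(path)

    day = MINUTES_PER_DAY
    emit("all_zero_day", np.zeros(day), np.full(day, int(State.BEDREST)))
    emit("all_active_day", np.full(day, 1500.0), np.full(day, int(State.WAKE)))

    for minutes in (29, 30, 90, 91):
        vm = np.full(360, 1500.0)
        vm[120 : 120 + minutes] = 0.0
        states = np.full(360, int(State.WAKE))
        states[120 : 120 + minutes] = int(State.BEDREST)
        emit(f"bedrest_{minutes}min", vm, states)

    for gap in (4, 5, 15, 16):
        vm = np.concatenate(
            [np.full(60, 1500.0), np.zeros(120), np.full(gap, 1500.0), np.zeros(120), np.full(60, 1500.0)]
        )
        states = np.where(vm == 0, int(State.BEDREST), int(State.WAKE))
        emit(f"wake_gap_{gap}min", vm, states)

    for name, zeros in (("nonwear_90min", 90), ("nonwear_89min", 89)):
        vm = np.concatenate([np.full(120, 1500.0), np.zeros(zeros), np.full(120, 1500.0)])
        states = np.full(len(vm), int(State.WAKE))
        if zeros >= 90:
            states[120 : 120 + zeros] = int(State.NONWEAR)
        emit(name, vm, states)

    vm = np.concatenate(
        [np.full(120, 1500.0), np.zeros(45), [50.0], np.zeros(45), np.full(120, 1500.0)]
    )
    states = np.full(len(vm), int(State.WAKE))
    states[120 : 120 + 91] = int(State.NONWEAR)
    emit("nonwear_spike_tolerated", vm, states)

    # Unlabeled plain fixture for reader round-trips.
    series, labels, _ = generate(SimProfile(n_days=2, seed=1))
    plain = out_dir / "synthetic_2day_plain.csv"
    write_plain_csv(series, plain)
    written.append(plain)
    truth = out_dir / "synthetic_2day_truth.csv"
    write_labeled_csv(series, labels, truth)
    written.append(truth)
    return written
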