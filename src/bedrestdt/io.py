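"""Readers and writers for epoch-count and labeled-output CSV files.

Two input dialects are supported:

``plain``
    A header row ``timestamp,axis1,axis2,axis3[,vm]`` followed by one
    ISO-8601-timestamped row per epoch.

``actigraph_header``
    An ActiLife epoch export: a metadata header block (``Start Time``,
    ``Start Date``, ``Epoch Period (hh:mm:ss)`` lines, with or without
    commas, terminated by a dashed line) followed by axis columns.
"""

from __future__ import annotations

import re
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AlignmentError,
    EpochSeries,
    Episode,
    FormatError,
    LabelSequence,
    State,
    ValidationError,
    compute_vector_magnitude,
)

__all__ = [
    "read_epoch_csv",
    "write_plain_csv",
    "write_labeled_csv",
    "read_labeled_csv",
    "write_episodes_csv",
]

_DASHED = re.compile(r"^-{5,}")
_HEADER_DATE_FORMATS = ("%m/%d/%Y", "%d/%m/%Y", "%Y-%m-%d")


def read_epoch_csv(path, dialect: str = "plain") -> EpochSeries:
    """Parse an epoch-count CSV in the given dialect into an EpochSeries."""
    path = Path(path)
    if dialect == "plain":
        return _read_plain(path)
    if dialect == "actigraph_header":
        return _read_actigraph(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_plain(path: Path) -> EpochSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed row structure
        raise FormatError(f"{path}: {exc}") from exc
    required = {"timestamp", "axis1", "axis2", "axis3"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: plain dialect needs columns {sorted(required)}")
    try:
        ts = pd.to_datetime(df["timestamp"])
    except Exception as exc:
        raise FormatError(f"{path}: unparseable timestamp column ({exc})") from exc
    if len(df) < 1:
        raise FormatError(f"{path}: no epoch rows")
    if len(df) > 1:
        deltas = np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(int)
        if (deltas <= 0).any():
            raise ValidationError(f"{path}: timestamps are not strictly increasing")
        if len(set(deltas)) > 1:
            raise ValidationError(
                f"{path}: gaps in the epoch grid (represent gaps as explicit rows)"
            )
        epoch_length = int(deltas[0])
    else:
        epoch_length = 60
    series = EpochSeries(
        start_time=ts.iloc[0].to_pydatetime(),
        axis1=df["axis1"].to_numpy(),
        axis2=df["axis2"].to_numpy(),
        axis3=df["axis3"].to_numpy(),
        epoch_length=epoch_length,
        meta={"source": str(path), "dialect": "plain"},
    )
    if "vm" in df.columns:
        given = df["vm"].to_numpy(dtype=float)
        if np.max(np.abs(given - series.vm)) > 1e-6:
            raise ValidationError(f"{path}: vm column inconsistent with axis counts")
    return series


def _parse_header_value(line: str, key: str) -> str:
    # ActiLife emits both "Start Time 21:00:00" and "Start Time,21:00:00".
    rest = line[len(key):].lstrip(" ,:\t")
    if not rest:
        raise FormatError(f"header line {line!r}: no value for {key!r}")
    return rest.split(",")[0].strip()


def _read_actigraph(path: Path) -> EpochSeries:
    lines = path.read_text().splitlines()
    if not lines or not _DASHED.match(lines[0]):
        raise FormatError(f"{path}: line 1: expected an ActiLife dashed header line")
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        if _DASHED.match(line):
            body_start = i  # 1-based line after the closing dashes
            break
        low = line.lower()
        for key in ("start time", "start date", "epoch period"):
            if low.startswith(key):
                header[key] = _parse_header_value(line, line[: len(key)])
    if body_start is None:
        raise FormatError(f"{path}: header block never closed by a dashed line")
    for key in ("start time", "start date", "epoch period"):
        if key not in header:
            raise FormatError(f"{path}: header lacks a '{key.title()}' line")

    m = re.search(r"(\d{1,2}):(\d{2}):(\d{2})", header["epoch period"])
    if not m:
        raise FormatError(f"{path}: unparseable epoch period {header['epoch period']!r}")
    epoch_length = int(m.group(1)) * 3600 + int(m.group(2)) * 60 + int(m.group(3))

    start = None
    for fmt in _HEADER_DATE_FORMATS:
        try:
            start = datetime.strptime(
                f"{header['start date']} {header['start time']}", f"{fmt} %H:%M:%S"
            )
            break
        except ValueError:
            continue
    if start is None:
        raise FormatError(
            f"{path}: unparseable start date/time "
            f"{header['start date']!r} {header['start time']!r}"
        )

    body = [ln for ln in lines[body_start:] if ln.strip()]
    if body and re.search(r"[A-Za-z]", body[0]):
        cols = [c.strip().lower() for c in body[0].split(",")]
        body = body[1:]
    else:
        cols = ["axis1", "axis2", "axis3"]
    rows = []
    width = None
    for offset, ln in enumerate(body):
        fields = [f.strip() for f in ln.split(",")]
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise FormatError(
                f"{path}: line {body_start + offset + (1 if cols else 0) + 1}: "
                f"expected {width} columns, got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric epoch row {ln!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no epoch rows after the header block")
    data = np.asarray(rows)

    def col(*names: str, default: int | None = None) -> np.ndarray:
        for name in names:
            if name in cols:
                return data[:, cols.index(name)]
        if default is not None:
            return data[:, default]
        raise FormatError(f"{path}: missing column(s) {names}")

    return EpochSeries(
        start_time=start,
        axis1=col("axis1", default=0),
        axis2=col("axis2", default=1),
        axis3=col("axis3", default=2),
        epoch_length=epoch_length,
        meta={"source": str(path), "dialect": "actigraph_header"},
    )


def write_plain_csv(series: EpochSeries, path) -> None:
    """Write a series in the plain dialect (round-trips through read_epoch_csv)."""
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "axis1": series.axis1,
            "axis2": series.axis2,
            "axis3": series.axis3,
            "vm": series.vm,
        }
    )
    df.to_csv(path, index=False)


def write_labeled_csv(series: EpochSeries, labels: LabelSequence, path) -> None:
    """One row per epoch: timestamp, axis counts, vm, state token.

    EXCLUDED epochs are serialized with the explicit ``excluded`` token,
    never left blank, so that read-back reproduces states exactly.
    """
    if len(labels) != len(series):
        raise AlignmentError("labels must align with the series")
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "axis1": series.axis1,
            "axis2": series.axis2,
            "axis3": series.axis3,
            "vm": series.vm,
            "state": labels.to_tokens(),
        }
    )
    df.to_csv(path, index=False)


def read_labeled_csv(path) -> tuple[EpochSeries, LabelSequence]:
    """Inverse of :func:`write_labeled_csv`."""
    df = pd.read_csv(path)
    if "state" not in df.columns:
        raise FormatError(f"{path}: labeled CSV needs a 'state' column")
    if df["state"].isna().any():
        raise ValidationError(f"{path}: blank state tokens are not allowed")
    series = _read_plain_frame(df, path)
    labels = LabelSequence.from_tokens(df["state"].astype(str))
    return series, labels


def _read_plain_frame(df: pd.DataFrame, path) -> EpochSeries:
    ts = pd.to_datetime(df["timestamp"])
    epoch_length = 60
    if len(df) > 1:
        epoch_length = int((ts.iloc[1] - ts.iloc[0]).total_seconds())
    return EpochSeries(
        start_time=ts.iloc[0].to_pydatetime(),
        axis1=df["axis1"].to_numpy(),
        axis2=df["axis2"].to_numpy(),
        axis3=df["axis3"].to_numpy(),
        epoch_length=epoch_length,
        meta={"source": str(path)},
    )


def write_episodes_csv(episodes: list[Episode], series: EpochSeries, path) -> None:
    """Episode table: state, start_time, end_time (exclusive), duration_min."""
    rows = [
        {
            "state": ep.state.token,
            "start_time": series.time_of(ep.start_index).isoformat(),
            "end_time": series.time_of(ep.end_index).isoformat(),
            "duration_min": ep.duration_min,
        }
        for ep in episodes
    ]
    pd.DataFrame(rows, columns=["state", "start_time", "end_time", "duration_min"]).to_csv(
        path, index=False
    )
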