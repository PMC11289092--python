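"""Readers and writers for E4-style session folders and interval/SQI CSVs.

The on-disk dialect follows the public Empatica E4 export convention:

* ``ACC.csv`` / ``EDA.csv`` / ``TEMP.csv`` / ``BVP.csv``: row 1 holds the
  session start time (UTC epoch seconds, repeated once per column), row 2
  the sample rate in Hz, and every following row one sample.  ACC samples
  are stored as raw integers in 1/64 g and converted to g on read.
* ``IBI.csv``: row 1 holds the session start time; following rows are
  ``(offset_seconds, ibi_seconds)`` pairs.
* ``tags.csv``: one epoch-second timestamp per row, no header.
* Interval CSVs carry columns ``label,start,end`` (epoch seconds,
  half-open); SQI CSVs carry ``timestamp,value`` with value in {0, 1}.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .timebase import (
    IntervalSet,
    IrregularSeries,
    Recording,
    SQISeries,
    UniformSeries,
    ValidationError,
)

__all__ = [
    "read_e4_session",
    "write_e4_session",
    "read_intervals",
    "write_intervals",
    "read_sqi",
    "write_sqi",
    "FormatError",
    "ACC_RAW_PER_G",
]

#: Raw accelerometer integer units per g in the E4 export.
ACC_RAW_PER_G = 64.0

_UNIFORM_CHANNELS = {
    "ACC": ("g", 3),
    "EDA": ("μS", 1),
    "TEMP": ("°C", 1),
    "BVP": ("a.u.", 1),
}


class FormatError(ValueError):
    """A session file does not match the expected CSV dialect."""


def _read_header_row(path: Path, row: str) -> float:
    try:
        return float(row.split(",")[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path.name}: malformed header row {row!r}") from exc


def _read_uniform_csv(path: Path, name: str, units: str, n_comp: int) -> UniformSeries:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path.name}: missing start-time/sample-rate header rows")
    start = _read_header_row(path, lines[0])
    rate = _read_header_row(path, lines[1])
    rows = []
    for ln in lines[2:]:
        parts = ln.split(",")
        if len(parts) != n_comp:
            raise FormatError(
                f"{path.name}: expected {n_comp} column(s), got row {ln!r}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-numeric sample row {ln!r}") from exc
    values = np.asarray(rows, dtype=float)
    if n_comp == 1:
        values = values.reshape(-1)
    else:
        values = values.reshape(-1, n_comp)
    if name == "ACC":
        values = values / ACC_RAW_PER_G
    return UniformSeries(name, start, rate, values, units)


def read_e4_session(path: str | os.PathLike) -> Recording:
    """Read an E4 session folder into a :class:`Recording`.

    The folder must contain at least one of ``ACC.csv``, ``EDA.csv`` or
    ``TEMP.csv``; optional channels (``BVP.csv``, ``IBI.csv``) and
    ``tags.csv`` are picked up when present and silently omitted otherwise.
    """
    folder = Path(path)
    if not folder.is_dir():
        raise ValidationError(f"no such session directory: {folder}")
    channels: dict = {}
    for name, (units, n_comp) in _UNIFORM_CHANNELS.items():
        f = folder / f"{name}.csv"
        if f.exists():
            channels[name] = _read_uniform_csv(f, name, units, n_comp)
    if not any(k in channels for k in ("ACC", "EDA", "TEMP")):
        raise ValidationError(
            f"{folder}: no ACC.csv, EDA.csv or TEMP.csv found"
        )
    ibi_file = folder / "IBI.csv"
    if ibi_file.exists():
        with open(ibi_file) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if not lines:
            raise FormatError("IBI.csv: empty file")
        start = _read_header_row(ibi_file, lines[0])
        pairs = []
        for ln in lines[1:]:
            parts = ln.split(",")
            if len(parts) != 2:
                raise FormatError(f"IBI.csv: expected 2 columns, got {ln!r}")
            try:
                pairs.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise FormatError(f"IBI.csv: non-numeric row {ln!r}") from exc
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
        channels["IBI"] = IrregularSeries("IBI", start + arr[:, 0], arr[:, 1])
    tags = np.empty(0)
    tags_file = folder / "tags.csv"
    if tags_file.exists():
        with open(tags_file) as fh:
            vals = [ln.strip() for ln in fh if ln.strip()]
        try:
            tags = np.asarray([float(v) for v in vals])
        except ValueError as exc:
            raise FormatError(f"tags.csv: non-numeric tag {exc}") from exc
    return Recording(
        participant_id=folder.name, session_id=folder.name,
        channels=channels, tags=tags,
    )


def write_e4_session(rec: Recording, path: str | os.PathLike) -> Path:
    """Write a :class:`Recording` in the dialect :func:`read_e4_session` reads.

    ACC values (g) are quantised to the raw integer 1/64 g grid, so a
    round-trip reproduces them within 1/128 g.
    """
    if not rec.channels:
        raise ValidationError("recording has no channels to write")
    folder = Path(path)
    folder.mkdir(parents=True, exist_ok=True)
    for name, series in rec.channels.items():
        f = folder / f"{name}.csv"
        if isinstance(series, IrregularSeries):
            with open(f, "w") as fh:
                if len(series):
                    start = series.timestamps[0]
                else:
                    start = 0.0
                fh.write(f"{float(start)!r}\n")
                for t, v in zip(series.timestamps, series.values):
                    fh.write(f"{float(t - start)!r},{float(v)!r}\n")
            continue
        vals = series.values
        if name == "ACC":
            vals = np.round(vals * ACC_RAW_PER_G).astype(int)
        vals2d = vals.reshape(len(series), -1)
        with open(f, "w") as fh:
            ncol = vals2d.shape[1]
            fh.write(",".join([repr(float(series.start_time))] * ncol) + "\n")
            fh.write(",".join([repr(float(series.sample_rate_hz))] * ncol) + "\n")
            for row in vals2d:
                fh.write(",".join(repr(float(v)) if vals2d.dtype.kind == "f"
                                  else str(int(v)) for v in row) + "\n")
    if len(rec.tags):
        with open(folder / "tags.csv", "w") as fh:
            for t in rec.tags:
                fh.write(f"{t!r}\n")
    return folder


def write_intervals(iv: IntervalSet, path: str | os.PathLike) -> Path:
    """Write an :class:`IntervalSet` as a ``label,start,end`` CSV."""
    df = pd.DataFrame(
        {
            "label": [iv.label] * len(iv),
            "start": iv.intervals[:, 0],
            "end": iv.intervals[:, 1],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_intervals(path: str | os.PathLike) -> IntervalSet:
    """Read a ``label,start,end`` CSV; invariants are re-validated on load."""
    df = pd.read_csv(path)
    for col in ("label", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    label = str(df["label"].iloc[0]) if len(df) else ""
    return IntervalSet(label, df[["start", "end"]].to_numpy(dtype=float))


def write_sqi(sqi: SQISeries, path: str | os.PathLike) -> Path:
    """Write an SQI as a ``timestamp,value`` CSV with 0/1 values."""
    df = pd.DataFrame(
        {"timestamp": sqi.timestamps(), "value": sqi.values.astype(int)}
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_sqi(path: str | os.PathLike, channel_name: str = "SQI") -> SQISeries:
    """Read a ``timestamp,value`` SQI CSV back to an :class:`SQISeries`.

    The rate is inferred from the median timestamp spacing.
    """
    df = pd.read_csv(path)
    ts = df["timestamp"].to_numpy(dtype=float)
    if len(ts) < 2:
        raise FormatError(f"{path}: need at least two samples to infer the rate")
    period = float(np.median(np.diff(ts)))
    return SQISeries(channel_name, ts[0], 1.0 / period,
                     df["value"].to_numpy() != 0)
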