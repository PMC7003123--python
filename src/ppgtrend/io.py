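"""Readers and writers for the pipeline's comma-separated-value dialects.

Three file formats, all UTF-8 with ``#``-prefixed comment lines skipped and
either LF or CRLF line endings:

* heart-rate files, header ``time_s,hr_bpm``;
* pulse-rate files, header ``time_s,pulse_bpm,device``;
* event annotation files, header ``onset_s,offset_s,label``.

Times are seconds from recording start, written to 1 ms; rates are written
to 0.1 bpm.  A heart-rate or pulse-rate file may instead carry an ISO-8601
wall-clock column named ``time_iso``; it is mapped to seconds relative to
the first sample on read.  Readers reject malformed input (citing the
offending data row) rather than repairing it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .series import AFEvent, Device, EventTable, HeartRateSeries, PulseSeries

logger = logging.getLogger(__name__)


def _read_table(path, expected: list[str], alt_time: bool = False) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file has no header row") from None
    cols = list(df.columns)
    accepted = [expected]
    if alt_time:
        accepted.append(["time_iso"] + expected[1:])
    if cols not in accepted:
        want = " or ".join(",".join(a) for a in accepted)
        raise ValidationError(
            f"{path}: unexpected header {','.join(cols)!r} (expected {want})"
        )
    if alt_time and cols[0] == "time_iso":
        ts = pd.to_datetime(df["time_iso"], utc=True, errors="raise")
        rel = (ts - ts.iloc[0]).dt.total_seconds() if len(ts) else ts
        df = df.drop(columns=["time_iso"])
        df.insert(0, expected[0], rel)
    return df


def read_hr_file(path) -> HeartRateSeries:
    """Read a 1-Hz heart-rate CSV into a validated :class:`HeartRateSeries`."""
    df = _read_table(path, ["time_s", "hr_bpm"], alt_time=True)
    if df.empty:
        logger.warning("%s: empty heart-rate data section", path)
        return HeartRateSeries(np.empty(0), np.empty(0))
    try:
        return HeartRateSeries(df["time_s"].to_numpy(), df["hr_bpm"].to_numpy())
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_hr_file(series: HeartRateSeries, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,hr_bpm\n")
        for t, h in zip(series.time_s, series.hr_bpm):
            fh.write(f"{t:.3f},{h:.1f}\n")


def read_pulse_file(path) -> PulseSeries:
    """Read a pulse-rate CSV into a validated :class:`PulseSeries`."""
    df = _read_table(path, ["time_s", "pulse_bpm", "device"], alt_time=True)
    if df.empty:
        logger.warning("%s: empty pulse-rate data section", path)
        return PulseSeries(np.empty(0), np.empty(0), device=None)
    devices = df["device"].astype(str).str.strip().unique().tolist()
    allowed = [d.value for d in Device]
    for d in devices:
        if d not in allowed:
            raise ValidationError(
                f"{path}: unknown device {d!r} (allowed: {', '.join(allowed)})"
            )
    if len(devices) > 1:
        raise ValidationError(
            f"{path}: mixed device tags {devices}; one device per file"
        )
    try:
        return PulseSeries(
            df["time_s"].to_numpy(),
            df["pulse_bpm"].to_numpy(),
            device=Device(devices[0]),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_pulse_file(series: PulseSeries, path) -> None:
    dev = series.device.value if series.device is not None else ""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,pulse_bpm,device\n")
        for t, p in zip(series.time_s, series.pulse_bpm):
            fh.write(f"{t:.3f},{p:.1f},{dev}\n")


def read_events(path) -> EventTable:
    """Read an AF event annotation CSV into a validated :class:`EventTable`."""
    df = _read_table(path, ["onset_s", "offset_s", "label"])
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            events.append(
                AFEvent(float(row.onset_s), float(row.offset_s), str(row.label))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    try:
        return EventTable(tuple(events))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_events(table: EventTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset_s,offset_s,label\n")
        for ev in table:
            fh.write(f"{ev.onset:.3f},{ev.offset:.3f},{ev.label}\n")
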