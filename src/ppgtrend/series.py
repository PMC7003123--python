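"""Core time-series containers.

The pipeline works on three kinds of records:

* a 1-Hz heart-rate stream derived from telemetric ECG (one sample per
  integer second, each the rate of the immediately preceding RR interval),
* an irregularly sampled pulse-rate stream from a wrist-worn PPG device,
* an annotation table of atrial-fibrillation (AF) episodes with onset and
  offset times.

All times are seconds from the start of the recording.  Rates are beats per
minute and must lie in the physiologic validation band [20, 300] bpm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Physiologic validation band for heart and pulse rates, bpm.
RATE_MIN = 20.0
RATE_MAX = 300.0


class Device(str, enum.Enum):
    """Pulse-rate source device / operating mode.

    FBT
        Fitbit Charge HR: pulse rate is the average of pulse signals
        captured over the last 2-5 s, emitted every 2-5 s.
    AWW
        Apple Watch in workout mode: a new rate every 5-6 s.
    AWS
        Apple Watch in standby mode: roughly one rate every 6 min, with
        intervals dispersed from about a second up to tens of minutes.
    """

    FBT = "FBT"
    AWW = "AWW"
    AWS = "AWS"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        row = int(np.flatnonzero(~np.isfinite(arr))[0]) + 1
        raise ValidationError(f"{name}: non-finite value at row {row}")
    return arr


def _check_strictly_increasing(t: np.ndarray, what: str) -> None:
    if t.size < 2:
        return
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        row = int(bad[0]) + 2  # 1-based row of the second of the pair
        raise ValidationError(
            f"{what}: times not strictly increasing at row {row} "
            f"(t={t[bad[0] + 1]:g} follows t={t[bad[0]]:g})"
        )


def _check_rate_band(r: np.ndarray, what: str) -> None:
    bad = np.flatnonzero((r < RATE_MIN) | (r > RATE_MAX))
    if bad.size:
        row = int(bad[0]) + 1
        raise ValidationError(
            f"{what}: rate {r[bad[0]]:g} bpm outside [{RATE_MIN:g}, "
            f"{RATE_MAX:g}] at row {row}"
        )


@dataclass(frozen=True)
class HeartRateSeries:
    """1-Hz ECG-derived heart-rate samples at integer-second times."""

    time_s: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self) -> None:
        t = _as_float_array(self.time_s, "time_s")
        h = _as_float_array(self.hr_bpm, "hr_bpm")
        if t.size != h.size:
            raise ValidationError("time_s and hr_bpm differ in length")
        _check_strictly_increasing(t, "heart-rate series")
        if t.size and not np.allclose(t, np.round(t), atol=1e-6):
            row = int(np.flatnonzero(~np.isclose(t, np.round(t), atol=1e-6))[0]) + 1
            raise ValidationError(
                f"heart-rate series: non-integer sample time at row {row}"
            )
        _check_rate_band(h, "heart-rate series")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "hr_bpm", h)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class PulseSeries:
    """Irregularly timestamped PPG pulse-rate samples with a device tag."""

    time_s: np.ndarray
    pulse_bpm: np.ndarray
    device: Device | None = None

    def __post_init__(self) -> None:
        t = _as_float_array(self.time_s, "time_s")
        p = _as_float_array(self.pulse_bpm, "pulse_bpm")
        if t.size != p.size:
            raise ValidationError("time_s and pulse_bpm differ in length")
        _check_strictly_increasing(t, "pulse series")
        _check_rate_band(p, "pulse series")
        if self.device is not None and not isinstance(self.device, Device):
            object.__setattr__(self, "device", Device(self.device))
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "pulse_bpm", p)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class AFEvent:
    """A single paroxysmal AF episode with telemetry-confirmed bounds."""

    onset: float
    offset: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.onset) and np.isfinite(self.offset)):
            raise ValidationError("event onset/offset must be finite")
        if not self.onset < self.offset:
            raise ValidationError(
                f"event offset ({self.offset:g}) must exceed onset "
                f"({self.onset:g})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class EventTable:
    """Ordered, non-overlapping AF episode annotations."""

    events: tuple[AFEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        evs = tuple(self.events)
        for i in range(1, len(evs)):
            if evs[i].onset < evs[i - 1].onset:
                raise ValidationError(
                    f"events not sorted by onset at row {i + 1}"
                )
            if evs[i].onset < evs[i - 1].offset:
                raise ValidationError(
                    f"events overlap at row {i + 1} "
                    f"(onset {evs[i].onset:g} < previous offset "
                    f"{evs[i - 1].offset:g})"
                )
        object.__setattr__(self, "events", evs)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)
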