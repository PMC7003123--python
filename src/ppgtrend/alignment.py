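"""Pairing and sliding-window trend construction.

The pulse-rate stream is irregular while the telemetry heart rate ticks
every second, so the two are compared *at the pulse-measurement times*:
each pulse reading p_x at time t_x is paired with the heart-rate sample at
the greatest integer second at or before t_x (a trailing match, consistent
with the telemetry rate itself being a trailing-RR quantity).  Sliding
windows of 10 consecutive pairs are then averaged into the two trend
curves (P, H), stepped one measurement at a time; frames whose wall-clock
span deviates largely from the nominal one minute are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, ParameterError
from .series import AFEvent, HeartRateSeries, PulseSeries

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 5.0  # s: oldest admissible heart-rate sample for pairing


@dataclass(frozen=True)
class PairedSamples:
    """Pulse readings with their matched heart rates, at pulse times."""

    t: np.ndarray  # seconds
    p: np.ndarray  # pulse rate, bpm
    h: np.ndarray  # matched heart rate, bpm

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class PairedTrend:
    """The two windowed trend curves.

    Point k holds P = mean pulse rate and H = mean heart rate over a frame
    of ``window_size`` consecutive pairs; ``t`` is the time of the frame's
    last pair and ``frame_duration`` its wall-clock span.
    """

    t: np.ndarray
    P: np.ndarray
    H: np.ndarray
    frame_duration: np.ndarray
    window_size: int = 10

    @property
    def n_points(self) -> int:
        return self.t.size

    def __len__(self) -> int:
        return self.t.size


def _empty_trend(window_size: int) -> PairedTrend:
    z = np.empty(0)
    return PairedTrend(z, z.copy(), z.copy(), z.copy(), window_size)


@dataclass(frozen=True)
class FramePolicy:
    """Admissible frame durations around the nominal one-minute frame."""

    nominal: float = 60.0
    min_duration: float = 30.0
    max_duration: float = 120.0

    def __post_init__(self) -> None:
        if not (0 < self.min_duration <= self.nominal <= self.max_duration):
            raise ParameterError(
                "need 0 < min_duration <= nominal <= max_duration"
            )


def pair_series(
    pulse: PulseSeries,
    hr: HeartRateSeries,
    max_gap: float = DEFAULT_MAX_GAP,
) -> PairedSamples:
    """Match each pulse reading with the most recent heart-rate sample.

    Pulse readings with no heart-rate sample at or before their time, or
    whose nearest sample is more than ``max_gap`` seconds older, are
    dropped (counts logged).  An empty result raises
    :class:`AlignmentError`.
    """
    if len(pulse) == 0 or len(hr) == 0:
        raise AlignmentError("both series must be non-empty")
    idx = np.searchsorted(hr.time_s, pulse.time_s, side="right") - 1
    ok = idx >= 0
    age = np.full(pulse.time_s.size, np.inf)
    age[ok] = pulse.time_s[ok] - hr.time_s[idx[ok]]
    ok &= age <= max_gap
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info(
            "pair_series: dropped %d of %d pulse samples with no heart-rate "
            "reference within %g s", n_drop, len(pulse), max_gap,
        )
    if not ok.any():
        raise AlignmentError("recordings do not overlap; no pairs formed")
    return PairedSamples(
        pulse.time_s[ok], pulse.pulse_bpm[ok], hr.hr_bpm[idx[ok]]
    )


def build_trend(pairs: PairedSamples, window_size: int = 10) -> PairedTrend:
    """Average sliding frames of consecutive pairs into the trend curves.

    Frame k covers pairs k .. k+window_size-1; the frame is stamped with
    its last pair's time.  Fewer pairs than one window yield an empty
    trend (warning logged).
    """
    if window_size < 2:
        raise ParameterError("window_size must be >= 2")
    n = len(pairs)
    if n < window_size:
        logger.warning(
            "build_trend: %d pairs < window of %d; empty trend", n, window_size
        )
        return _empty_trend(window_size)
    w = window_size
    kern = np.ones(w)
    P = np.convolve(pairs.p, kern, mode="valid") / w
    H = np.convolve(pairs.h, kern, mode="valid") / w
    t_last = pairs.t[w - 1:]
    frame_duration = t_last - pairs.t[: n - w + 1]
    return PairedTrend(t_last, P, H, frame_duration, w)


def filter_frames(trend: PairedTrend, policy: FramePolicy | None = None) -> PairedTrend:
    """Drop frames whose duration falls outside the policy band."""
    policy = policy or FramePolicy()
    keep = (trend.frame_duration >= policy.min_duration) & (
        trend.frame_duration <= policy.max_duration
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "filter_frames: removed %d of %d frames outside [%g, %g] s",
            n_drop, trend.n_points, policy.min_duration, policy.max_duration,
        )
    return PairedTrend(
        trend.t[keep], trend.P[keep], trend.H[keep],
        trend.frame_duration[keep], trend.window_size,
    )


def restrict_to_event(trend: PairedTrend, event: AFEvent) -> PairedTrend:
    """Keep frames lying wholly within [onset, offset].

    Whole-frame containment avoids frames that straddle an onset or offset
    and so mix AF and sinus beats.  An empty result is allowed.
    """
    t_first = trend.t - trend.frame_duration
    keep = (t_first >= event.onset) & (trend.t <= event.offset)
    return PairedTrend(
        trend.t[keep], trend.P[keep], trend.H[keep],
        trend.frame_duration[keep], trend.window_size,
    )
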