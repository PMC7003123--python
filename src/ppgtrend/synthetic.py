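"""Synthetic coupled ECG/PPG recordings with known ground truth.

The validation analysis needs pairs of recordings that share one underlying
cardiac rhythm: a 1-Hz telemetry heart-rate stream and an irregularly
sampled device pulse-rate stream.  This module generates them from first
principles:

1. a beat-level rhythm model produces R-peak times (sinus rhythm with
   Gaussian RR jitter, AF with independent Gamma-distributed RR intervals,
   both riding on a slow sinusoidal rate drift shared by the whole
   recording — the smooth multi-minute trends seen on bedside telemetry);
2. an optional pulse-deficit model thins beats that fail to produce an
   effective peripheral pulse, with the transmitted fraction falling as the
   instantaneous ventricular rate rises;
3. a device model samples the perfused beat train the way a wrist PPG
   watch does — trailing-window averaging at irregular intervals, additive
   measurement noise, optional gain error, dropout, and a "decorrelated"
   hypotension regime in which readings no longer track the heart at all.

All operations are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, ScheduleError
from .series import AFEvent, Device, HeartRateSeries, PulseSeries, RATE_MAX, RATE_MIN

__all__ = [
    "RhythmParams",
    "DeviceModel",
    "DeficitModel",
    "BeatSeries",
    "simulate_sinus_rr",
    "simulate_af_rr",
    "compose_recording",
    "derive_telemetry_hr",
    "apply_pulse_deficit",
    "sample_device",
    "simulate_af_event",
]

#: Admissible single-RR range, seconds.  Draws outside are rejected.
RR_MIN = 0.2
RR_MAX = 5.0
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class RhythmParams:
    """Rhythm model parameters.

    Parameters
    ----------
    mean_hr_sinus
        Mean sinus heart rate, bpm.
    hrv_cv_sinus
        Coefficient of variation of sinus RR intervals (beat-to-beat
        jitter on top of the slow drift).
    mean_hr_af
        Mean ventricular rate during AF, bpm.
    rr_cv_af
        Coefficient of variation of AF RR intervals.  AF is irregularly
        irregular: this is several-fold larger than the sinus CV.
    hr_drift_amplitude
        Amplitude of the slow sinusoidal rate drift, expressed in bpm at
        the AF mean rate.  The drift is multiplicative — autonomic tone
        scales the rate — so the instantaneous rate is
        ``base * (1 + (hr_drift_amplitude / mean_hr_af) * sin(...))``
        and a slower base rhythm drifts proportionally less.  Telemetry
        trend curves during postoperative AF meander over tens of bpm on
        a multi-minute scale; the drift is the shared slow signal both
        the ECG and the PPG device observe.
    hr_drift_period
        Period of the drift, seconds.
    """

    mean_hr_sinus: float = 75.0
    hrv_cv_sinus: float = 0.05
    mean_hr_af: float = 110.0
    rr_cv_af: float = 0.25
    hr_drift_amplitude: float = 15.0
    hr_drift_period: float = 300.0

    def __post_init__(self) -> None:
        if self.mean_hr_sinus <= 0 or self.mean_hr_af <= 0:
            raise ParameterError("mean heart rates must be positive")
        if self.hrv_cv_sinus < 0 or self.rr_cv_af < 0:
            raise ParameterError("coefficients of variation must be >= 0")
        if self.hr_drift_amplitude < 0:
            raise ParameterError("hr_drift_amplitude must be >= 0")
        if self.hr_drift_period <= 0:
            raise ParameterError("hr_drift_period must be positive")
        if self.hr_drift_amplitude >= self.mean_hr_af:
            raise ParameterError(
                "hr_drift_amplitude must be smaller than mean_hr_af"
            )


@dataclass(frozen=True)
class DeviceModel:
    """PPG device sampling model.

    ``dt_min``/``dt_max`` bound the interval between consecutive pulse-rate
    computations; FBT and AWW draw gaps uniformly from that band, while AWS
    draws them from a heavy-tailed log-normal clipped to it.  Each reading
    averages the instantaneous rates (60/RR) of the beats in the trailing
    ``averaging_window`` seconds, is scaled by ``gain``, and receives
    additive Gaussian noise of ``noise_sd`` bpm.  ``decorrelate`` switches
    the device into a regime where readings are drawn around
    ``baseline_mean`` independently of the beat train — emulating the loss
    of a usable peripheral signal seen during hypotension.
    """

    mode: Device
    dt_min: float
    dt_max: float
    averaging_window: float
    noise_sd: float = 2.0
    dropout_prob: float = 0.0
    gain: float = 1.0
    decorrelate: bool = False
    baseline_mean: float = 70.0
    baseline_sd: float = 5.0

    # Log-normal gap parameters for standby mode: mean exp(mu + sigma^2/2)
    # ~ 394 s with a spread covering ~1 s up to tens of minutes.
    _AWS_LOG_MU = 5.0
    _AWS_LOG_SIGMA = 1.4

    def __post_init__(self) -> None:
        if not isinstance(self.mode, Device):
            object.__setattr__(self, "mode", Device(self.mode))
        if not (0 < self.dt_min <= self.dt_max):
            raise ParameterError("need 0 < dt_min <= dt_max")
        if self.averaging_window <= 0:
            raise ParameterError("averaging_window must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise ParameterError("dropout_prob must be in [0, 1)")
        if self.gain <= 0:
            raise ParameterError("gain must be positive")
        if self.baseline_sd < 0 or self.baseline_mean <= 0:
            raise ParameterError("invalid decorrelated baseline")

    @classmethod
    def fbt(cls, **overrides) -> "DeviceModel":
        """Fitbit Charge HR: averages pulse signals over 2-5 s."""
        return cls(mode=Device.FBT, dt_min=2.0, dt_max=5.0,
                   averaging_window=5.0, **overrides)

    @classmethod
    def aww(cls, **overrides) -> "DeviceModel":
        """Apple Watch workout mode: a reading every 5-6 s."""
        return cls(mode=Device.AWW, dt_min=5.0, dt_max=6.0,
                   averaging_window=5.0, **overrides)

    @classmethod
    def aws(cls, **overrides) -> "DeviceModel":
        """Apple Watch standby mode: sparse, wildly dispersed intervals."""
        return cls(mode=Device.AWS, dt_min=1.0, dt_max=39.0 * 60.0,
                   averaging_window=8.0, **overrides)


@dataclass(frozen=True)
class DeficitModel:
    """Pulse-deficit model: probability that a ventricular beat produces an
    effective peripheral pulse, anchored at 80 and 120 bpm and log-linearly
    interpolated in between (clamped to (0, 1] outside).

    Defaults follow animal-model observations that the effective (pulse)
    rate is ~96.8% of the electrical rate at 80 bpm and ~92.5% at 120 bpm.
    """

    transmit_frac_at_80: float = 0.968
    transmit_frac_at_120: float = 0.925

    def __post_init__(self) -> None:
        for v in (self.transmit_frac_at_80, self.transmit_frac_at_120):
            if not (0 < v <= 1):
                raise ParameterError("transmit fractions must be in (0, 1]")
        if self.transmit_frac_at_120 > self.transmit_frac_at_80:
            raise ParameterError(
                "transmit fraction must not increase with rate"
            )

    def transmit_prob(self, rate_bpm) -> np.ndarray:
        """Transmission probability at an instantaneous rate (bpm)."""
        rate = np.asarray(rate_bpm, dtype=float)
        la, lb = math.log(self.transmit_frac_at_80), math.log(self.transmit_frac_at_120)
        logp = la + (rate - 80.0) / 40.0 * (lb - la)
        return np.minimum(np.exp(logp), 1.0)


@dataclass(frozen=True)
class BeatSeries:
    """Ordered R-peak timestamps (seconds); the simulation ground truth."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        if t.ndim != 1:
            raise ParameterError("beat_times must be one-dimensional")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ParameterError("beat_times must be strictly increasing")
        object.__setattr__(self, "beat_times", t)

    def __len__(self) -> int:
        return self.beat_times.size

    @property
    def rr_intervals(self) -> np.ndarray:
        """Consecutive RR intervals, seconds."""
        return np.diff(self.beat_times)

    @property
    def instantaneous_rate(self) -> np.ndarray:
        """60/RR for each completed interval, bpm (length n_beats - 1)."""
        return 60.0 / self.rr_intervals


class _DrawBuffer:
    """Block-buffered scalar draws from a numpy Generator (keeps the beat
    loop cheap without changing the stream for a given seed)."""

    def __init__(self, fill, block: int = 2048):
        self._fill = fill
        self._block = block
        self._arr = fill(block)
        self._i = 0

    def next(self) -> float:
        if self._i >= self._arr.size:
            self._arr = self._fill(self._block)
            self._i = 0
        v = self._arr[self._i]
        self._i += 1
        return float(v)


def _generate_beats(
    schedule: list[AFEvent],
    params: RhythmParams,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequentially generate beat times on [0, duration].

    Inside a scheduled event RR intervals follow the AF Gamma model; outside
    they follow the sinus Gaussian-jitter model.  Both share one slow drift
    term with a random phase so the recording has a single continuous rate
    trend.
    """
    if duration < 0:
        raise ParameterError("duration must be >= 0")
    if duration == 0:
        return np.empty(0)

    period = params.hr_drift_period
    depth = params.hr_drift_amplitude / params.mean_hr_af  # modulation depth
    phase = float(rng.uniform(0.0, 2.0 * math.pi)) if depth > 0 else 0.0
    two_pi = 2.0 * math.pi

    cv_s = params.hrv_cv_sinus
    cv_af = params.rr_cv_af
    normal_buf = _DrawBuffer(lambda n: rng.standard_normal(n)) if cv_s > 0 else None
    if cv_af > 0:
        shape = 1.0 / (cv_af * cv_af)
        gamma_buf = _DrawBuffer(lambda n: rng.gamma(shape, 1.0 / shape, size=n))
    else:
        gamma_buf = None

    onsets = np.array([ev.onset for ev in schedule])
    offsets = np.array([ev.offset for ev in schedule])
    n_ev = onsets.size
    ev_i = 0

    beats = [0.0]
    t = 0.0
    while True:
        while ev_i < n_ev and t >= offsets[ev_i]:
            ev_i += 1
        in_af = ev_i < n_ev and t >= onsets[ev_i]

        base = params.mean_hr_af if in_af else params.mean_hr_sinus
        rate = base * (
            1.0 + depth * math.sin(two_pi * t / period + phase)
        ) if depth else base
        mu = 60.0 / rate

        for attempt in range(_MAX_REDRAWS + 1):
            if in_af:
                factor = gamma_buf.next() if gamma_buf else 1.0
            else:
                factor = 1.0 + cv_s * normal_buf.next() if normal_buf else 1.0
            rr = mu * factor
            if RR_MIN < rr < RR_MAX:
                break
        else:
            raise ParameterError(
                "could not draw an RR interval inside "
                f"[{RR_MIN}, {RR_MAX}] s after {_MAX_REDRAWS} attempts "
                f"(rate {rate:g} bpm)"
            )
        if t + rr > duration + 1e-9:
            break
        t += rr
        beats.append(t)
    return np.asarray(beats)


def simulate_sinus_rr(params: RhythmParams, duration: float, seed: int) -> BeatSeries:
    """Simulate a sinus-rhythm beat train.

    RR intervals are Gaussian around 60/``mean_hr_sinus`` with CV
    ``hrv_cv_sinus``, modulated by the slow drift term.
    """
    rng = np.random.default_rng(seed)
    return BeatSeries(_generate_beats([], params, duration, rng))


def simulate_af_rr(params: RhythmParams, duration: float, seed: int) -> BeatSeries:
    """Simulate an AF beat train.

    RR intervals are drawn from a Gamma distribution with mean
    60/``mean_hr_af`` and CV ``rr_cv_af``; successive Gamma innovations are
    independent (the "irregularly irregular" ventricular response), with
    only the slow drift term introducing a weak shared trend.
    """
    rng = np.random.default_rng(seed)
    if duration == 0:
        return BeatSeries(np.empty(0))
    schedule = [AFEvent(0.0, duration + 1.0, "af")]
    return BeatSeries(_generate_beats(schedule, params, duration, rng))


def compose_recording(
    schedule: list[AFEvent],
    params: RhythmParams,
    duration: float,
    seed: int,
) -> tuple[BeatSeries, list[AFEvent]]:
    """Build a paroxysmal recording: sinus rhythm with scheduled AF episodes.

    Beat times are continuous across regime boundaries.  Returns the beat
    train and the (validated, sorted) schedule.
    """
    evs = sorted(schedule, key=lambda e: e.onset)
    for i, ev in enumerate(evs):
        if ev.onset < 0 or ev.offset > duration:
            raise ScheduleError(
                f"event {ev.label or i + 1!r} outside [0, {duration:g}] s"
            )
        if i and ev.onset < evs[i - 1].offset:
            raise ScheduleError(
                f"events overlap at onset {ev.onset:g} s"
            )
    rng = np.random.default_rng(seed)
    beats = _generate_beats(evs, params, duration, rng)
    return BeatSeries(beats), list(evs)


def derive_telemetry_hr(beats: BeatSeries, duration: float) -> HeartRateSeries:
    """Telemetry heart rate: one sample per integer second, each equal to
    60/RR of the interval completed immediately before that second.

    Emission starts at the first integer second with at least two beats
    strictly before it; there is no backfill.  Fewer than two beats yield
    an empty series.
    """
    b = beats.beat_times
    if b.size < 2:
        return HeartRateSeries(np.empty(0), np.empty(0))
    t_start = int(math.floor(b[1])) + 1
    t_end = int(math.floor(duration))
    if t_end < t_start:
        return HeartRateSeries(np.empty(0), np.empty(0))
    t_grid = np.arange(t_start, t_end + 1, dtype=float)
    # index of last beat strictly before each grid second
    idx = np.searchsorted(b, t_grid, side="left") - 1
    hr = 60.0 / (b[idx] - b[idx - 1])
    return HeartRateSeries(t_grid, hr)


def apply_pulse_deficit(
    beats: BeatSeries, model: DeficitModel, seed: int
) -> BeatSeries:
    """Thin a beat train by the pulse-deficit model.

    Each beat is retained independently with the transmission probability
    evaluated at its instantaneous rate (60 over the preceding RR; the
    first beat uses the following interval).  Ordering is preserved.
    """
    b = beats.beat_times
    if b.size == 0:
        return BeatSeries(b.copy())
    rng = np.random.default_rng(seed)
    if b.size == 1:
        keep = rng.random(1) < model.transmit_prob(60.0)  # no rate defined
        return BeatSeries(b[keep] if keep.any() else np.empty(0))
    rate = np.empty(b.size)
    rate[1:] = 60.0 / np.diff(b)
    rate[0] = rate[1]
    p = model.transmit_prob(rate)
    keep = rng.random(b.size) < p
    return BeatSeries(b[keep])


def _draw_sample_times(
    model: DeviceModel, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Sequential sample times: cumulative sums of per-reading gaps."""
    mean_gap = (
        min(math.exp(model._AWS_LOG_MU + model._AWS_LOG_SIGMA**2 / 2), model.dt_max)
        if model.mode is Device.AWS
        else 0.5 * (model.dt_min + model.dt_max)
    )
    times: list[np.ndarray] = []
    total = 0.0
    while total <= duration:
        n = max(16, int((duration - total) / mean_gap * 1.25) + 8)
        if model.mode is Device.AWS:
            gaps = rng.lognormal(model._AWS_LOG_MU, model._AWS_LOG_SIGMA, size=n)
            gaps = np.clip(gaps, model.dt_min, model.dt_max)
        else:
            gaps = rng.uniform(model.dt_min, model.dt_max, size=n)
        block = total + np.cumsum(gaps)
        times.append(block)
        total = float(block[-1])
    t = np.concatenate(times)
    return t[t <= duration]


def sample_device(
    beats: BeatSeries, model: DeviceModel, duration: float, seed: int
) -> PulseSeries:
    """Sample a beat train the way a PPG watch reports pulse rate.

    Each reading at time ``t`` is the mean instantaneous rate (60/RR) of
    the beats completed in the trailing ``averaging_window``, scaled by
    ``gain`` plus Gaussian noise; readings whose window holds no completed
    beat are omitted, and each reading is independently lost with
    ``dropout_prob``.  In the decorrelated (hypotension) regime readings
    are drawn around the device baseline, independent of the beats.
    """
    rng = np.random.default_rng(seed)
    t = _draw_sample_times(model, duration, rng)
    if t.size == 0:
        return PulseSeries(np.empty(0), np.empty(0), device=model.mode)

    if model.decorrelate:
        values = rng.normal(model.baseline_mean, model.baseline_sd, size=t.size)
        if model.noise_sd > 0:
            values = values + rng.normal(0.0, model.noise_sd, size=t.size)
        valid = np.ones(t.size, dtype=bool)
    else:
        b = beats.beat_times
        if b.size < 2:
            return PulseSeries(np.empty(0), np.empty(0), device=model.mode)
        rate = 60.0 / np.diff(b)  # rate attributed to the interval's end beat
        csum = np.concatenate([[0.0], np.cumsum(rate)])
        # beats (interval ends) with time in (t - window, t]
        lo = np.searchsorted(b[1:], t - model.averaging_window, side="right")
        hi = np.searchsorted(b[1:], t, side="right")
        count = hi - lo
        valid = count > 0
        values = np.full(t.size, np.nan)
        values[valid] = (csum[hi[valid]] - csum[lo[valid]]) / count[valid]
        values[valid] *= model.gain
        if model.noise_sd > 0:
            values[valid] += rng.normal(0.0, model.noise_sd, size=int(valid.sum()))

    if model.dropout_prob > 0:
        valid &= rng.random(t.size) >= model.dropout_prob

    values = np.clip(values[valid], RATE_MIN, RATE_MAX)
    return PulseSeries(t[valid], values, device=model.mode)


def simulate_af_event(
    rhythm: RhythmParams,
    device: DeviceModel,
    duration: float,
    seed: int,
    deficit: DeficitModel | None = None,
) -> tuple[HeartRateSeries, PulseSeries]:
    """Convenience composite: one AF episode observed by telemetry and by a
    PPG device.

    The telemetry stream sees every electrical beat; the device sees the
    (optionally deficit-thinned) perfused beat train.
    """
    rng = np.random.default_rng(seed)
    s_beat, s_def, s_dev = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    event = AFEvent(0.0, duration + 1.0, "af")
    beats = BeatSeries(
        _generate_beats([event], rhythm, duration, np.random.default_rng(s_beat))
    )
    perfused = apply_pulse_deficit(beats, deficit, s_def) if deficit else beats
    hr = derive_telemetry_hr(beats, duration)
    pulse = sample_device(perfused, device, duration, s_dev)
    return hr, pulse
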