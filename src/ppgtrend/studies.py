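"""Seeded synthetic-recovery experiments.

These run the full pipeline (simulate one AF episode -> pair -> trend ->
frame filter -> statistic) many times and report how often the analysis
recovers the planted structure.  They back the package's calibration
checks and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .alignment import FramePolicy, build_trend, filter_frames, pair_series
from .ccf import CCFResult, ccf_trend
from .regression import event_accuracy, fit_accuracy_regression
from .synthetic import DeviceModel, RhythmParams, simulate_af_event

__all__ = [
    "run_ccf_recovery_study",
    "run_slope_recovery_study",
    "event_ccf",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def event_ccf(
    rhythm: RhythmParams,
    device: DeviceModel,
    duration: float,
    seed: int,
    policy: FramePolicy | None = None,
) -> CCFResult:
    """Simulate one AF episode and run it through the CCF pipeline."""
    hr, pulse = simulate_af_event(rhythm, device, duration, seed)
    pairs = pair_series(pulse, hr)
    trend = filter_frames(build_trend(pairs), policy)
    return ccf_trend(trend)


def run_ccf_recovery_study(
    n_events: int = 100,
    duration: float = 3600.0,
    seed: int = 0,
    rhythm: RhythmParams | None = None,
    device: DeviceModel | None = None,
) -> list[CCFResult]:
    """CCFs of ``n_events`` independently simulated AF episodes.

    Defaults: one-hour episodes observed by an Apple-Watch-workout-like
    device at its default noise level.
    """
    rhythm = rhythm or RhythmParams()
    device = device or DeviceModel.aww()
    return [
        event_ccf(rhythm, device, duration, int(s))
        for s in _child_seeds(seed, n_events)
    ]


def run_slope_recovery_study(
    n_replicates: int = 100,
    n_events: int = 30,
    gain: float = 0.85,
    duration: float = 1800.0,
    seed: int = 0,
    rhythm: RhythmParams | None = None,
) -> list[float]:
    """Recover a planted device attenuation from the mean-accuracy fit.

    Each replicate simulates ``n_events`` AF episodes whose mean
    ventricular rates are spread uniformly over 90-130 bpm, observed by a
    device whose readings are scaled by ``gain``; the slope of the
    across-event regression of mean pulse rate on mean heart rate is the
    estimate of ``gain``.  Returns one fitted slope per replicate.
    """
    base = rhythm or RhythmParams()
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_replicates):
        events = []
        for i in range(n_events):
            mean_af = float(rng.uniform(90.0, 130.0))
            rp = RhythmParams(
                mean_hr_sinus=base.mean_hr_sinus,
                hrv_cv_sinus=base.hrv_cv_sinus,
                mean_hr_af=mean_af,
                rr_cv_af=base.rr_cv_af,
                hr_drift_amplitude=base.hr_drift_amplitude,
                hr_drift_period=base.hr_drift_period,
            )
            device = DeviceModel.aww(gain=gain)
            s = int(rng.integers(0, 2**31 - 1))
            hr, pulse = simulate_af_event(rp, device, duration, s)
            trend = filter_frames(build_trend(pair_series(pulse, hr)))
            events.append(event_accuracy(trend, i, device.mode.value))
        slopes.append(fit_accuracy_regression(events, "mean").slope)
    return slopes
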