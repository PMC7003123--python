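"""Per-event accuracy statistics and across-event agreement regression.

For each AF event the trend curves are reduced to four numbers: the mean
and sample standard deviation of the averaged pulse rates (X and A) and of
the corresponding averaged heart rates (Y and B).  Device accuracy is then
summarized by simple linear regression *of the pulse statistic on the
heart-rate statistic* across events — X = a + bY for the means, A = a + bB
for the standard deviations — so a perfectly accurate device gives slope
1, intercept 0, R^2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .alignment import PairedTrend
from .exceptions import InsufficientDataError, ParameterError, RegressionError


@dataclass(frozen=True)
class EventAccuracy:
    """Mean/SD of the P and H trend values within one AF event."""

    event_id: object
    device: str
    mean_P: float
    mean_H: float
    sd_P: float
    sd_H: float
    n_points: int


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of pulse statistic on heart statistic."""

    intercept: float
    slope: float
    r_squared: float
    p_value: float  # two-sided t test on the slope
    n_events: int


def event_accuracy(trend: PairedTrend, event_id, device) -> EventAccuracy:
    """Reduce an event's trend to per-event mean/SD accuracy inputs.

    Standard deviations use the sample (n-1) denominator.  Fewer than two
    trend points raise :class:`InsufficientDataError`.
    """
    n = trend.n_points
    if n < 2:
        raise InsufficientDataError(
            f"event accuracy needs >= 2 trend points, got {n}"
        )
    return EventAccuracy(
        event_id=event_id,
        device=str(device),
        mean_P=float(np.mean(trend.P)),
        mean_H=float(np.mean(trend.H)),
        sd_P=float(np.std(trend.P, ddof=1)),
        sd_H=float(np.std(trend.H, ddof=1)),
        n_points=n,
    )


def fit_accuracy_regression(
    events: list[EventAccuracy], statistic: str
) -> RegressionFit:
    """Regress the per-event pulse statistic on the heart-rate statistic.

    Parameters
    ----------
    events
        Per-event accuracy records (one device).
    statistic
        ``"mean"`` regresses mean_P on mean_H (the X = a + bY fit);
        ``"sd"`` regresses sd_P on sd_H (the A = a + bB fit).
    """
    if statistic not in ("mean", "sd"):
        raise ParameterError("statistic must be 'mean' or 'sd'")
    if len(events) < 3:
        raise RegressionError(
            f"regression needs >= 3 events, got {len(events)}"
        )
    if statistic == "mean":
        x = np.array([e.mean_H for e in events])
        y = np.array([e.mean_P for e in events])
    else:
        x = np.array([e.sd_H for e in events])
        y = np.array([e.sd_P for e in events])
    if np.std(x) == 0:
        raise RegressionError("predictor has zero variance across events")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n_events=len(events),
    )
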