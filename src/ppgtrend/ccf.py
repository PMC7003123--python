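"""Residual cross-correlation of the two trend curves.

The similarity statistic is a three-step cross-correlation function (CCF):

1. regress each trend curve (P and H) on time by ordinary least squares,
2. take the residuals at each point,
3. compute the Pearson correlation between the two residual series.

The linear detrend is a single-regression prewhitening: it removes the
shared deterministic drift so the correlation reflects co-movement of the
fluctuations rather than a common trend.  The p-value is the usual
two-sided t test for a Pearson correlation, r * sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom; serial dependence of the residuals is ignored.

Correlation strength is binned as: negative (< 0), very weak [0, 0.2),
weak [0.2, 0.4), moderate [0.4, 0.6), strong [0.6, 0.8), very strong
[0.8, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import PairedTrend
from .exceptions import (
    InsufficientDataError,
    ParameterError,
    UndefinedCorrelationError,
)

MODERATE_THRESHOLD = 0.40  # "moderate or higher" cut used in summaries
_VAR_TOL = 1e-12


class StrengthClass(enum.IntEnum):
    """Correlation strength bins, totally ordered weakest-to-strongest
    (with negative correlations kept as their own lowest class)."""

    negative = 0
    very_weak = 1
    weak = 2
    moderate = 3
    strong = 4
    very_strong = 5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class CCFResult:
    """Cross-correlation of one event's trend curves."""

    ccf: float
    p_value: float
    n_points: int
    strength: StrengthClass


def detrend_linear(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Residuals of an ordinary least-squares fit of values on time."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ParameterError("times and values differ in length")
    if t.size < 3:
        raise InsufficientDataError("need at least 3 points to detrend")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("times must be strictly increasing")
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    return v - A @ coef


def ccf_trend(trend: PairedTrend) -> CCFResult:
    """Three-step CCF between a trend's P and H curves.

    Raises :class:`UndefinedCorrelationError` if either residual series has
    (numerically) zero variance — a perfectly linear curve has no
    fluctuation to correlate.
    """
    n = trend.n_points
    if n < 3:
        raise InsufficientDataError(
            f"CCF needs at least 3 trend points, got {n}"
        )
    res_p = detrend_linear(trend.t, trend.P)
    res_h = detrend_linear(trend.t, trend.H)
    scale_p = float(np.max(np.abs(trend.P))) or 1.0
    scale_h = float(np.max(np.abs(trend.H))) or 1.0
    if np.std(res_p) <= _VAR_TOL * scale_p or np.std(res_h) <= _VAR_TOL * scale_h:
        raise UndefinedCorrelationError(
            "a residual series has zero variance; CCF undefined"
        )
    r, p = stats.pearsonr(res_p, res_h)
    r = float(np.clip(r, -1.0, 1.0))
    return CCFResult(r, float(p), n, classify_strength(r))


def classify_strength(ccf: float) -> StrengthClass:
    """Bin a correlation coefficient into its strength class."""
    if not np.isfinite(ccf) or abs(ccf) > 1 + 1e-9:
        raise ParameterError(f"correlation {ccf!r} outside [-1, 1]")
    if ccf < 0:
        return StrengthClass.negative
    if ccf < 0.2:
        return StrengthClass.very_weak
    if ccf < 0.4:
        return StrengthClass.weak
    if ccf < 0.6:
        return StrengthClass.moderate
    if ccf < 0.8:
        return StrengthClass.strong
    return StrengthClass.very_strong


def summarize_events(
    results: list[tuple[object, str, CCFResult]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-event CCFs and per-device strength counts.

    Parameters
    ----------
    results
        Tuples of (event_id, device, :class:`CCFResult`).

    Returns
    -------
    events, counts
        ``events``: one row per (event, device), ordered by event_id.
        ``counts``: per device, the number and fraction of events with
        CCF above the moderate threshold (> 0.40) and the number showing
        only a very weak or negative correlation.
    """
    rows = [
        {
            "event_id": ev,
            "device": str(dev),
            "n_points": res.n_points,
            "ccf": res.ccf,
            "p_value": res.p_value,
            "strength": res.strength.name,
        }
        for ev, dev, res in results
    ]
    events = pd.DataFrame(
        rows,
        columns=["event_id", "device", "n_points", "ccf", "p_value", "strength"],
    )
    if len(events):
        events = events.sort_values(["event_id", "device"], kind="stable")
        events = events.reset_index(drop=True)

    crows = []
    for dev in sorted(events["device"].unique()) if len(events) else []:
        sub = events[events["device"] == dev]
        n = len(sub)
        n_mod = int((sub["ccf"] > MODERATE_THRESHOLD).sum())
        n_weak = int(sub["strength"].isin(["negative", "very_weak"]).sum())
        crows.append(
            {
                "device": dev,
                "n_events": n,
                "n_moderate_or_higher": n_mod,
                "frac_moderate_or_higher": n_mod / n if n else 0.0,
                "n_very_weak_or_negative": n_weak,
            }
        )
    counts = pd.DataFrame(
        crows,
        columns=[
            "device",
            "n_events",
            "n_moderate_or_higher",
            "frac_moderate_or_higher",
            "n_very_weak_or_negative",
        ],
    )
    return events, counts
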