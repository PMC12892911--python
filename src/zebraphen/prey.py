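"""Prey-capture analysis: rotifer depletion and hunting-event detection.

A free-swimming larva is monitored with live rotifers.  Two readouts are
quantified:

1. **Depletion** — the observed rotifer count is median-filtered over a
   10-s rolling window (removing single-frame segmentation dropouts),
   normalized to the mean count over the first minute, and subtracted
   from 1 to give the proportion of rotifers consumed.  Group
   comparisons use the value at a representative time point (15 min,
   when wild-type capture slows due to satiation).

2. **Hunting events** — larvae converge their eyes (> 60 deg summed
   nasal rotation) when pursuing prey.  An event starts at a bout in
   which the eyes *become* converged and runs through the maximal
   sequence of subsequent bouts at whose onset the eyes are *still*
   converged, ending at the last such bout's end.  Events are summarized
   in 5-min intervals (count and mean duration).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    BoutIntervals,
    EyeConvergenceTrace,
    HuntingEvent,
    RotiferCountSeries,
)
from .errors import DataValidationError

#: Eye-convergence criterion for hunting, in degrees.
CONVERGENCE_THRESHOLD_DEG = 60.0


def rolling_median(
    series: RotiferCountSeries, window_s: float = 10.0
) -> RotiferCountSeries:
    """Centered rolling median over a time window.

    For each sample at time t the median is taken over all samples in
    [t - w/2, t + w/2]; at the edges the window truncates to the
    available samples (no padding, so early depletion is unbiased).
    """
    if window_s <= 0:
        raise DataValidationError(f"window_s must be > 0, got {window_s}")
    t, c = series.t, series.count
    half = window_s / 2.0
    # tolerance keeps samples lying exactly on a window boundary inside
    # the window despite float rounding of regular time grids
    eps = 1e-9 * window_s
    lo = np.searchsorted(t, t - half - eps, side="left")
    hi = np.searchsorted(t, t + half + eps, side="right")
    out = np.array([np.median(c[a:b]) for a, b in zip(lo, hi)])
    return RotiferCountSeries(t=t.copy(), count=out)


def proportion_consumed(filtered: RotiferCountSeries) -> pd.DataFrame:
    """Proportion of rotifers consumed: p(t) = 1 - count(t)/baseline.

    The baseline is the mean filtered count over the first 60 s.
    Values are not clamped; negative excursions are flagged in the
    ``below_zero`` QC column rather than hidden.
    """
    t, c = filtered.t, filtered.count
    if t[-1] - t[0] < 60.0:
        raise DataValidationError("series must cover at least 60 s for the baseline")
    baseline = float(c[t <= t[0] + 60.0].mean())
    if baseline <= 0:
        raise DataValidationError(f"first-minute baseline must be > 0, got {baseline}")
    p = 1.0 - c / baseline
    return pd.DataFrame({"t": t, "proportion_consumed": p, "below_zero": p < 0})


def proportion_at(proportions: pd.DataFrame, t_s: float = 900.0) -> float:
    """Proportion consumed at the frame nearest ``t_s`` (ties -> earlier)."""
    t = proportions["t"].to_numpy()
    if t_s < t[0] or t_s > t[-1]:
        raise DataValidationError(f"t={t_s} s outside series span [{t[0]}, {t[-1]}]")
    d = np.abs(t - t_s)
    i = int(np.argmin(d))  # argmin returns the first (earlier) minimum on ties
    return float(proportions["proportion_consumed"].iloc[i])


def detect_hunting_events(
    convergence: EyeConvergenceTrace,
    bouts: BoutIntervals,
    threshold_deg: float = CONVERGENCE_THRESHOLD_DEG,
) -> list[HuntingEvent]:
    """Detect bout-aligned hunting events from eye convergence.

    A bout is *converging* if convergence at its onset is at or below
    threshold but rises above it during the bout; it is
    *still-converged* if convergence at its onset is already above
    threshold.  Each event starts at a converging bout and extends
    through the maximal run of immediately following still-converged
    bouts, ending at that last bout's end.  Events never overlap and are
    aligned to bout boundaries by construction.
    """
    t, conv = convergence.t, convergence.convergence_deg
    if len(bouts) == 0:
        if np.any(conv > threshold_deg):
            warnings.warn(
                "super-threshold eye convergence with no swim bouts: "
                "no hunting events can be assigned",
                stacklevel=2,
            )
        return []

    def onset_conv(start: float) -> float:
        return convergence.at(start)

    def max_in(start: float, end: float) -> float:
        a = np.searchsorted(t, start, side="left")
        b = np.searchsorted(t, end, side="left")
        if a >= b:
            return onset_conv(start)
        return float(conv[a:b].max())

    events: list[HuntingEvent] = []
    open_start: float | None = None
    open_end = 0.0
    n_bouts = 0
    for start, end in bouts:
        at_onset = onset_conv(start)
        still = at_onset > threshold_deg
        converging = (not still) and max_in(start, end) > threshold_deg
        if open_start is not None and still:
            open_end = end
            n_bouts += 1
            continue
        if open_start is not None:
            events.append(HuntingEvent(open_start, open_end, n_bouts))
            open_start = None
        if converging:
            open_start, open_end, n_bouts = start, end, 1
    if open_start is not None:
        events.append(HuntingEvent(open_start, open_end, n_bouts))
    return events


def interval_summary(
    events: list[HuntingEvent], total_s: float = 900.0, bin_s: float = 300.0
) -> pd.DataFrame:
    """Per-interval hunting-event count and mean duration.

    An event belongs to the bin containing its start.  Empty bins report
    n_events = 0 and NaN mean duration (undefined, not zero).
    """
    n_bins = int(np.ceil(total_s / bin_s))
    starts = np.array([e.start_s for e in events])
    durations = np.array([e.duration_s for e in events])
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_s, (b + 1) * bin_s
        mask = (starts >= lo) & (starts < hi) if len(events) else np.empty(0, bool)
        n = int(mask.sum()) if len(events) else 0
        rows.append(
            {
                "bin_start_s": lo,
                "bin_end_s": min(hi, total_s),
                "n_events": n,
                "mean_duration_s": float(durations[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
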