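"""Tail-bout segmentation and cohort kinematic summaries.

Bouts are segmented from the tail-angle trace by hysteresis thresholding
of the smoothed absolute angular speed; bout *vigor* is the RMS angular
velocity (deg/s) within the bout — the simplest monotone intensity
measure, pinned by a closed-form sinusoid test (RMS derivative of
A*sin(2*pi*f*t) is A*2*pi*f/sqrt(2)).

Cohort summaries mirror the standard open-arena figures: bout frequency
per larva, vigor probability density with a pointwise 95% bootstrap CI,
and a binned mobility timecourse with a 99% bootstrap CI plus a
divergence mask marking bins where two groups' intervals are disjoint.
Bootstrap resampling is always at the individual (larva) level, never
per bout, because bouts within a larva are not independent.

"Mobility" is implemented as the fraction of each time bin occupied by
bouts — a convention, since the underlying trajectory measure is not
uniquely defined by the assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import BoutIntervals
from .errors import DataValidationError, InsufficientDataError


@dataclass(frozen=True)
class BoutRecord:
    """One segmented tail bout with its RMS angular velocity."""

    start_s: float
    end_s: float
    vigor: float  # deg/s

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise DataValidationError("bout end must exceed start")
        if self.vigor < 0:
            raise DataValidationError("vigor must be >= 0")


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    # reflect-pad so the smoothed trace keeps its length and edges
    pad = width // 2
    xp = np.pad(x, pad, mode="reflect")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return out


def segment_bouts(
    t: np.ndarray,
    angle_deg: np.ndarray,
    smooth_ms: float = 15.0,
    on_thresh_deg_s: Optional[float] = None,
    off_thresh_deg_s: Optional[float] = None,
    min_dur_ms: float = 40.0,
    min_gap_ms: float = 20.0,
) -> list[BoutRecord]:
    """Segment swim bouts from a uniformly sampled tail-angle trace.

    The absolute angular speed |d(angle)/dt| is smoothed with a
    ``smooth_ms`` moving average; a bout opens when the smoothed speed
    exceeds ``on_thresh_deg_s`` and closes when it falls below
    ``off_thresh_deg_s`` (hysteresis).  Bouts shorter than
    ``min_dur_ms`` are dropped; bouts separated by less than
    ``min_gap_ms`` are merged.  When thresholds are not given they
    default to 5x (on) and 2x (off) the median absolute deviation of
    the smoothed speed — a robust noise-floor convention.
    """
    t = np.asarray(t, dtype=float)
    angle = np.asarray(angle_deg, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError("trace too short to segment")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise DataValidationError("tail trace must be uniformly sampled")
    speed_raw = np.abs(np.gradient(angle, dt))
    width = max(int(round(smooth_ms / 1000.0 / dt)), 1)
    speed = _moving_average(speed_raw, width)

    if on_thresh_deg_s is None or off_thresh_deg_s is None:
        mad = float(stats.median_abs_deviation(speed))
        med = float(np.median(speed))
        if on_thresh_deg_s is None:
            on_thresh_deg_s = med + 5.0 * max(mad, 1e-9)
        if off_thresh_deg_s is None:
            off_thresh_deg_s = med + 2.0 * max(mad, 1e-9)
    if not on_thresh_deg_s >= off_thresh_deg_s > 0:
        raise DataValidationError("require on_thresh >= off_thresh > 0")

    # hysteresis state machine over the smoothed speed
    intervals: list[list[int]] = []
    in_bout = False
    start = 0
    for i, s in enumerate(speed):
        if not in_bout and s > on_thresh_deg_s:
            in_bout, start = True, i
        elif in_bout and s < off_thresh_deg_s:
            intervals.append([start, i])
            in_bout = False
    if in_bout:
        intervals.append([start, len(speed)])

    # merge bouts separated by short gaps, then drop short bouts
    min_gap = min_gap_ms / 1000.0 / dt
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < min_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    min_dur = min_dur_ms / 1000.0 / dt
    records = []
    for a, b in merged:
        if b - a < min_dur:
            continue
        vigor = float(np.sqrt(np.mean(speed_raw[a:b] ** 2)))
        records.append(BoutRecord(start_s=t[a], end_s=t[min(b, len(t) - 1)], vigor=vigor))
    return records


def bout_frequency(bouts: Sequence[BoutRecord], recording_duration_s: float) -> float:
    """Bouts per minute over the recording."""
    if recording_duration_s <= 0:
        raise DataValidationError("recording duration must be > 0")
    return 60.0 * len(bouts) / recording_duration_s


def _percentile_band(samples: np.ndarray, ci: float) -> tuple[np.ndarray, np.ndarray]:
    alpha = (100.0 - ci) / 2.0
    return (
        np.percentile(samples, alpha, axis=0),
        np.percentile(samples, 100.0 - alpha, axis=0),
    )


def vigor_density(
    vigors_by_individual: Sequence[np.ndarray],
    grid: np.ndarray,
    n_boot: int = 1000,
    ci: float = 95.0,
    seed: int = 0,
) -> dict:
    """Vigor probability density with a pointwise bootstrap CI band.

    ``vigors_by_individual`` holds one array of bout vigors per larva.
    The density is a Gaussian KDE of the pooled vigors evaluated on
    ``grid``; the CI comes from a percentile bootstrap that resamples
    larvae (with replacement), never individual bouts.
    """
    groups = [np.asarray(v, dtype=float) for v in vigors_by_individual]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise InsufficientDataError("vigor density needs >= 2 individuals with bouts")
    grid = np.asarray(grid, dtype=float)
    pooled = np.concatenate(groups)
    density = stats.gaussian_kde(pooled)(grid)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        idx = rng.integers(0, len(groups), size=len(groups))
        sample = np.concatenate([groups[i] for i in idx])
        if len(np.unique(sample)) < 2:
            boot[b] = density
            continue
        boot[b] = stats.gaussian_kde(sample)(grid)
    lo, hi = _percentile_band(boot, ci)
    return {"grid": grid, "density": density, "ci_lo": lo, "ci_hi": hi}


def bout_occupancy(
    bouts: BoutIntervals | Sequence[BoutRecord],
    duration_s: float,
    bin_s: float,
) -> np.ndarray:
    """Fraction of each [k*bin, (k+1)*bin) bin occupied by bouts."""
    if isinstance(bouts, BoutIntervals):
        arr = bouts.array
    else:
        arr = np.array([[b.start_s, b.end_s] for b in bouts]).reshape(-1, 2)
    n_bins = int(np.ceil(duration_s / bin_s))
    occ = np.zeros(n_bins)
    for s, e in arr:
        b0 = int(s // bin_s)
        b1 = int(min(np.ceil(e / bin_s), n_bins))
        for b in range(b0, b1):
            lo, hi = b * bin_s, min((b + 1) * bin_s, duration_s)
            occ[b] += max(0.0, min(e, hi) - max(s, lo))
    widths = np.minimum((np.arange(n_bins) + 1) * bin_s, duration_s) - np.arange(
        n_bins
    ) * bin_s
    return occ / widths


def mobility_timecourse(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 1000,
    ci: float = 99.0,
    seed: int = 0,
) -> dict:
    """Group mobility timecourse with bootstrap CI and divergence mask.

    Each group is an (n_larvae, n_bins) matrix of per-larva mobility
    (e.g. bout-occupancy fraction per bin).  Group means carry a
    percentile bootstrap CI over larvae; the divergence mask marks bins
    where the two groups' intervals are disjoint.  The mask is
    symmetric in group order.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("each group needs >= 2 larvae")
    if a.shape[1] != b.shape[1]:
        raise DataValidationError("groups must share the bin grid")
    out = {}
    for name, mat in (("a", a), ("b", b)):
        # each group restarts the stream at `seed`, so the result is
        # exactly symmetric under swapping the two groups
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, mat.shape[1]))
        for k in range(n_boot):
            idx = rng.integers(0, mat.shape[0], size=mat.shape[0])
            boot[k] = mat[idx].mean(axis=0)
        lo, hi = _percentile_band(boot, ci)
        out[f"mean_{name}"] = mat.mean(axis=0)
        out[f"lo_{name}"], out[f"hi_{name}"] = lo, hi
    mask = (out["lo_a"] > out["hi_b"]) | (out["lo_b"] > out["hi_a"])
    out["divergence_mask"] = mask
    return out
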