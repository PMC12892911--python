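"""Light-flash-response (LFR) and spontaneous-activity metrics.

Input is a per-well actinteg trace on the 1/15-s slice grid.  Two
protocols are supported:

* **simple** — 300 s dark then 10 s light.  The light response is
  scored over the first 4 s of light only (afterwards larvae freeze
  with movements near zero): maximal slice amplitude and number of
  movement events.
* **extended** — 300 s dark adaptation, 600 s spontaneous window, then
  8 cycles of 1 s light + 29 s dark.  V1 is the triggered average
  (actinteg per second) over the first 2 s after each flash onset, V2
  over the following 28 s of dark, each averaged across the 8 flashes
  with equal weight.

An "event" is a maximal run of consecutive slices at or above an
activity threshold; runs separated by at most ``merge_gap_slices``
sub-threshold slices are merged.  The threshold is an explicit analysis
parameter (see :func:`default_threshold` for the documented convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import SLICES_PER_SECOND, ActivityTrace, StimulusProtocol
from .errors import DataValidationError, ProtocolMismatchError

#: Response window of the simple protocol, in seconds after light onset.
LFR_WINDOW_S = 4.0


@dataclass(frozen=True)
class LfrMetrics:
    """Summary of a simple-protocol light-flash response."""

    max_activity: float
    n_events: int
    window_s: float = LFR_WINDOW_S


@dataclass
class TriggeredResponse:
    """Flash-triggered averages of the extended protocol.

    ``per_flash`` is an 8x2 matrix of per-flash (V1, V2) values in
    actinteg per second; ``v1``/``v2`` are their unweighted column means.
    """

    v1: float
    v2: float
    per_flash: np.ndarray


def detect_events(
    values: np.ndarray, threshold: float, merge_gap_slices: int = 0
) -> int:
    """Count movement events: threshold-runs merged across short gaps."""
    if threshold <= 0:
        raise DataValidationError(f"threshold must be > 0, got {threshold}")
    above = np.asarray(values) >= threshold
    if not above.any():
        return 0
    # run starts/ends of the boolean mask
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    if merge_gap_slices > 0:
        merged = 1
        for i in range(1, len(starts)):
            if starts[i] - ends[i - 1] > merge_gap_slices:
                merged += 1
        return merged
    return len(starts)


def default_threshold(trace: ActivityTrace) -> float:
    """Data-driven event threshold: 3x the median dark-epoch nonzero slice.

    Falls back to 1.0 when the dark epochs contain no activity at all.
    """
    onsets = trace.protocol.epoch_onsets_s()
    dark = []
    t = 0.0
    for onset, (kind, dur) in zip(onsets, trace.protocol.epochs):
        if kind == "dark":
            i0 = trace.protocol.slice_of(onset)
            i1 = i0 + int(round(dur * SLICES_PER_SECOND))
            dark.append(trace.values[i0:i1])
        t += dur
    dark_values = np.concatenate(dark) if dark else np.empty(0)
    nonzero = dark_values[dark_values > 0]
    if len(nonzero) == 0:
        return 1.0
    return 3.0 * float(np.median(nonzero))


def _light_epoch_start(protocol: StimulusProtocol) -> float:
    for onset, (kind, _) in zip(protocol.epoch_onsets_s(), protocol.epochs):
        if kind == "light":
            return onset
    raise ProtocolMismatchError("protocol has no light epoch")


def lfr_simple(
    trace: ActivityTrace, threshold: float, merge_gap_slices: int = 0
) -> LfrMetrics:
    """Score the light-flash response of a simple-protocol trace.

    Analyzes exactly the first 4 s (60 slices) of the light epoch:
    ``max_activity`` is the largest slice value in the window and
    ``n_events`` the merged threshold-run count.
    """
    proto = trace.protocol
    if proto.name != "simple":
        raise ProtocolMismatchError(
            f"lfr_simple requires the simple protocol, got {proto.name!r}"
        )
    i0 = proto.slice_of(_light_epoch_start(proto))
    i1 = i0 + int(LFR_WINDOW_S * SLICES_PER_SECOND)
    window = trace.values[i0:i1]
    return LfrMetrics(
        max_activity=float(window.max()),
        n_events=detect_events(window, threshold, merge_gap_slices),
    )


def triggered_average(
    trace: ActivityTrace,
    flash_onsets_s: list[float] | None = None,
) -> TriggeredResponse:
    """Compute V1/V2 flash-triggered averages of an extended-protocol trace.

    Per flash, V1 = mean actinteg per second over [onset, onset + 2 s)
    (the 1-s light pulse is included) and V2 over [onset + 2 s,
    onset + 30 s).  V1/V2 are the unweighted means across flashes.
    """
    proto = trace.protocol
    if flash_onsets_s is None:
        flash_onsets_s = proto.flash_onsets_s()
    if not flash_onsets_s:
        raise ProtocolMismatchError("no flash onsets in protocol")
    n_v1 = 2 * SLICES_PER_SECOND
    n_v2 = 28 * SLICES_PER_SECOND
    per_flash = np.empty((len(flash_onsets_s), 2))
    for k, onset in enumerate(flash_onsets_s):
        i0 = proto.slice_of(onset)
        if i0 + n_v1 + n_v2 > len(trace.values):
            raise DataValidationError(
                f"flash at {onset} s: 30-s window exceeds trace end"
            )
        per_flash[k, 0] = trace.values[i0 : i0 + n_v1].sum() / 2.0
        per_flash[k, 1] = trace.values[i0 + n_v1 : i0 + n_v1 + n_v2].sum() / 28.0
    return TriggeredResponse(
        v1=float(per_flash[:, 0].mean()),
        v2=float(per_flash[:, 1].mean()),
        per_flash=per_flash,
    )


def spontaneous_activity(trace: ActivityTrace) -> float:
    """Mean actinteg per second over the 600-s spontaneous window.

    The window is the extended protocol's second dark epoch (the first
    300 s of dark adaptation are excluded).
    """
    proto = trace.protocol
    if proto.name != "extended":
        raise ProtocolMismatchError(
            f"spontaneous_activity requires the extended protocol, got {proto.name!r}"
        )
    onsets = proto.epoch_onsets_s()
    i0 = proto.slice_of(onsets[1])
    i1 = i0 + int(round(proto.epochs[1][1] * SLICES_PER_SECOND))
    return float(trace.values[i0:i1].mean() * SLICES_PER_SECOND)
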