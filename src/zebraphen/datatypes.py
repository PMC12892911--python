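"""Core data containers shared across the pipeline.

Activity traces are sampled on a fixed 1/15-s slice grid (the ZebraLab
"actinteg" convention: each slice value is the sum of all pixel changes
detected during that slice).  The slice duration is carried as the exact
rational 1/15 so that slice/second conversions never accumulate float
drift over long protocols.

All intervals (bouts, hunting events, analysis bins) are half-open
``[start, end)`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, ProtocolMismatchError

#: Exact slice duration of the activity recorder, as a rational.
SLICE_DURATION: Fraction = Fraction(1, 15)

#: Slices per second (the reciprocal of SLICE_DURATION).
SLICES_PER_SECOND: int = 15

GENOTYPES = ("wt", "het", "hom")

EpochKind = Literal["dark", "light"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered sequence of dark/light epochs driving an activity assay.

    Two named protocols are used throughout:

    * ``simple``   — 300 s dark acclimatization + 10 s light; the
      light-flash response (LFR) is scored in the first 4 s of light.
    * ``extended`` — 300 s dark adaptation + 600 s dark spontaneous
      window + 8 cycles of (1 s light + 29 s dark) for triggered
      averaging (V1/V2).

    Epoch durations must be whole numbers of 1/15-s slices.
    """

    epochs: tuple[tuple[EpochKind, float], ...]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise DataValidationError("protocol must contain at least one epoch")
        for i, (kind, dur) in enumerate(self.epochs):
            if kind not in ("dark", "light"):
                raise DataValidationError(f"epoch {i}: unknown kind {kind!r}")
            if not dur > 0:
                raise DataValidationError(f"epoch {i}: duration must be > 0, got {dur}")
            frac = Fraction(dur).limit_denominator(10**6) * SLICES_PER_SECOND
            if frac.denominator != 1:
                raise DataValidationError(
                    f"epoch {i}: duration {dur} s is not a whole number of 1/15-s slices"
                )

    @classmethod
    def simple(cls) -> "StimulusProtocol":
        return cls(epochs=(("dark", 300.0), ("light", 10.0)), name="simple")

    @classmethod
    def extended(cls) -> "StimulusProtocol":
        flashes: list[tuple[EpochKind, float]] = []
        for _ in range(8):
            flashes += [("light", 1.0), ("dark", 29.0)]
        return cls(
            epochs=(("dark", 300.0), ("dark", 600.0), *flashes), name="extended"
        )

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.epochs))

    @property
    def n_slices(self) -> int:
        total = sum(
            Fraction(d).limit_denominator(10**6) * SLICES_PER_SECOND
            for _, d in self.epochs
        )
        assert total.denominator == 1
        return int(total)

    def epoch_onsets_s(self) -> list[float]:
        """Start time of every epoch, in seconds."""
        onsets, t = [], Fraction(0)
        for _, d in self.epochs:
            onsets.append(float(t))
            t += Fraction(d).limit_denominator(10**6)
        return onsets

    def flash_onsets_s(self) -> list[float]:
        """Onset times of all light epochs."""
        return [
            t for t, (kind, _) in zip(self.epoch_onsets_s(), self.epochs)
            if kind == "light"
        ]

    def slice_of(self, t_s: float) -> int:
        """Index of the slice containing time ``t_s`` (exact for epoch onsets)."""
        frac = Fraction(t_s).limit_denominator(10**6) * SLICES_PER_SECOND
        return int(frac)


@dataclass
class ActivityTrace:
    """Per-well actinteg time series on the protocol's slice grid."""

    well_id: str
    values: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataValidationError(f"well {self.well_id}: values must be 1-D")
        if len(self.values) != self.protocol.n_slices:
            raise ProtocolMismatchError(
                f"well {self.well_id}: trace has {len(self.values)} slices but "
                f"protocol {self.protocol.name or '<custom>'} requires "
                f"{self.protocol.n_slices}"
            )
        if np.any(self.values < 0):
            i = int(np.argmax(self.values < 0))
            raise DataValidationError(
                f"well {self.well_id}: negative actinteg at slice {i}"
            )

    def __len__(self) -> int:
        return len(self.values)


class BoutIntervals:
    """Sorted, non-overlapping half-open swim-bout intervals in seconds."""

    def __init__(self, intervals: Sequence[tuple[float, float]] | np.ndarray):
        arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
        if len(arr):
            if np.any(arr[:, 1] <= arr[:, 0]):
                bad = int(np.argmax(arr[:, 1] <= arr[:, 0]))
                raise DataValidationError(
                    f"bout {bad}: end {arr[bad, 1]} <= start {arr[bad, 0]}"
                )
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                bad = int(np.argmax(arr[1:, 0] < arr[:-1, 1]))
                raise DataValidationError(
                    f"bouts overlap: ({arr[bad, 0]}, {arr[bad, 1]}) and "
                    f"({arr[bad + 1, 0]}, {arr[bad + 1, 1]})"
                )
        self.array = arr

    def __len__(self) -> int:
        return len(self.array)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        for s, e in self.array:
            yield float(s), float(e)

    def __getitem__(self, i: int) -> tuple[float, float]:
        s, e = self.array[i]
        return float(s), float(e)

    @property
    def durations(self) -> np.ndarray:
        if not len(self.array):
            return np.empty(0)
        return self.array[:, 1] - self.array[:, 0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BoutIntervals):
            return NotImplemented
        return self.array.shape == other.array.shape and bool(
            np.allclose(self.array, other.array)
        )

    def __repr__(self) -> str:
        return f"BoutIntervals(n={len(self)})"


def _strictly_increasing(t: np.ndarray, what: str) -> None:
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise DataValidationError(
            f"{what}: time not strictly increasing at index {i + 1} "
            f"(t={t[i]} followed by t={t[i + 1]})"
        )


@dataclass
class RotiferCountSeries:
    """Observed rotifer counts over time (one value per frame or bin)."""

    t: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if self.t.shape != self.count.shape:
            raise DataValidationError("rotifer counts: t and count lengths differ")
        _strictly_increasing(self.t, "rotifer counts")
        if np.any(self.count < 0):
            i = int(np.argmax(self.count < 0))
            raise DataValidationError(f"rotifer counts: negative count at row {i}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class EyeConvergenceTrace:
    """Summed nasal eye-rotation angle (degrees) over time.

    Sustained convergence above ~60 deg marks prey pursuit; the hunting
    detector consumes this trace together with the bout intervals.
    """

    t: np.ndarray
    convergence_deg: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.convergence_deg = np.asarray(self.convergence_deg, dtype=float)
        if self.t.shape != self.convergence_deg.shape:
            raise DataValidationError("convergence: t and angle lengths differ")
        _strictly_increasing(self.t, "convergence")
        if not np.all(np.isfinite(self.convergence_deg)):
            i = int(np.argmax(~np.isfinite(self.convergence_deg)))
            raise DataValidationError(f"convergence: non-finite angle at row {i}")

    def __len__(self) -> int:
        return len(self.t)

    def at(self, t_s: float) -> float:
        """Angle at the last sample with time <= t_s (step interpolation)."""
        i = int(np.searchsorted(self.t, t_s, side="right")) - 1
        if i < 0:
            i = 0
        return float(self.convergence_deg[i])


@dataclass(frozen=True)
class HuntingEvent:
    """Bout-aligned interval of sustained eye convergence."""

    start_s: float
    end_s: float
    n_bouts: int

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise DataValidationError(
                f"hunting event: end {self.end_s} <= start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class PlateFluorescence:
    """Per-well fluorescence readings with optional known genotypes.

    Thin wrapper around a DataFrame with columns ``well``,
    ``fluorescence`` and (optionally) ``true_genotype``.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"well", "fluorescence"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"plate table missing columns: {sorted(missing)}")
        df = df.reset_index(drop=True).copy()
        if df["well"].duplicated().any():
            dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
            raise DataValidationError(f"duplicate well id {dup!r}")
        fl = pd.to_numeric(df["fluorescence"], errors="coerce")
        if fl.isna().any() or not np.all(np.isfinite(fl.to_numpy())):
            i = int(np.argmax(~np.isfinite(fl.to_numpy(dtype=float))))
            raise DataValidationError(f"non-finite fluorescence at row {i}")
        df["fluorescence"] = fl.astype(float)
        if "true_genotype" in df.columns:
            known = df["true_genotype"].dropna()
            bad = ~known.isin(GENOTYPES)
            if bad.any():
                raise DataValidationError(
                    f"unknown genotype {known[bad].iloc[0]!r} "
                    f"(expected one of {GENOTYPES})"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def wells(self) -> pd.Series:
        return self.df["well"]

    @property
    def fluorescence(self) -> np.ndarray:
        return self.df["fluorescence"].to_numpy()

    @property
    def has_truth(self) -> bool:
        return "true_genotype" in self.df.columns and self.df["true_genotype"].notna().all()


@dataclass
class OCRTrace:
    """Oxygen-consumption-rate series with injection marks.

    ``fccp_index`` is the first measurement taken after the FCCP
    (uncoupler) injection; ``raa_index`` the first after rotenone +
    antimycin A.  At least 3 pre-FCCP points, 1 inter-injection point
    and 2 post-R+AA points are required for the decomposition.
    """

    t_min: np.ndarray
    ocr: np.ndarray
    fccp_index: int
    raa_index: int
    well_id: str = "w1"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        n = len(self.ocr)
        if self.t_min.shape != self.ocr.shape:
            raise DataValidationError(f"well {self.well_id}: t_min/ocr length mismatch")
        _strictly_increasing(self.t_min, f"well {self.well_id} OCR")
        if not (0 < self.fccp_index < self.raa_index < n):
            raise DataValidationError(
                f"well {self.well_id}: injection indices must satisfy "
                f"0 < fccp ({self.fccp_index}) < raa ({self.raa_index}) < n ({n})"
            )
        if self.fccp_index < 3:
            raise DataValidationError(
                f"well {self.well_id}: need >= 3 pre-FCCP points, got {self.fccp_index}"
            )
        if self.raa_index - self.fccp_index < 1:
            raise DataValidationError(
                f"well {self.well_id}: need >= 1 point between FCCP and R+AA"
            )
        if n - self.raa_index < 2:
            raise DataValidationError(
                f"well {self.well_id}: need >= 2 post-R+AA points, "
                f"got {n - self.raa_index}"
            )

    def __len__(self) -> int:
        return len(self.ocr)
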