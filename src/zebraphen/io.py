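"""Readers and writers for the pipeline's tabular formats, plus run config.

One canonical CSV dialect is used everywhere: comma-separated, UTF-8,
header row required, ``.`` decimal separator, no thousands separators.
Readers validate and reject malformed input — they never repair it —
and error messages carry row/column provenance.

Formats:

* activity CSV      — ``well,slice_index,actinteg`` (0-based contiguous
  slice indices per well on the 1/15-s grid)
* tracking tables   — ``t,count`` / ``t,convergence_deg`` /
  ``bout_start,bout_end`` (seconds)
* OCR CSV           — ``well,t_min,ocr`` plus injection indices in the
  run config (``fccp_index``, ``raa_index``)
* plate CSV         — ``well,fluorescence[,true_genotype]``
* survival CSV      — ``subject,group,time,event``
* run config        — flat ``key=value`` text
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ActivityTrace,
    BoutIntervals,
    EyeConvergenceTrace,
    OCRTrace,
    PlateFluorescence,
    RotiferCountSeries,
    StimulusProtocol,
)
from .errors import (
    DataValidationError,
    FormatError,
    ProtocolMismatchError,
)

VERBOSITY_LEVELS = ("quiet", "info", "debug")


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands.

    ``slice_duration_lfr`` is pinned to the exact rational 1/15 s (the
    recorder's slice); ``sampling_rate_behavior`` is the kinematics
    camera frame rate, which the behavior rig leaves configurable.
    """

    sampling_rate_behavior: float = 700.0
    rng_seed: int = 0
    output_dir: Path = Path(".")
    verbosity: str = "info"
    slice_duration_lfr: Fraction = field(default=Fraction(1, 15), init=False)

    def __post_init__(self) -> None:
        if self.sampling_rate_behavior <= 0:
            raise DataValidationError("sampling_rate_behavior must be > 0")
        if self.verbosity not in VERBOSITY_LEVELS:
            raise DataValidationError(
                f"verbosity must be one of {VERBOSITY_LEVELS}, got {self.verbosity!r}"
            )
        self.output_dir = Path(self.output_dir)

    def save(self, path: str | Path) -> None:
        lines = [
            f"sampling_rate_behavior={self.sampling_rate_behavior}",
            "slice_duration_lfr=1/15",
            f"rng_seed={self.rng_seed}",
            f"output_dir={self.output_dir}",
            f"verbosity={self.verbosity}",
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        kv = {}
        for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {i + 1}: expected key=value")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        if kv.get("slice_duration_lfr", "1/15") != "1/15":
            raise DataValidationError(
                f"{path}: slice_duration_lfr must be exactly 1/15"
            )
        return cls(
            sampling_rate_behavior=float(kv.get("sampling_rate_behavior", 700.0)),
            rng_seed=int(kv.get("rng_seed", 0)),
            output_dir=Path(kv.get("output_dir", ".")),
            verbosity=kv.get("verbosity", "info"),
        )


METRIC_VOCABULARY = frozenset(
    {
        "max_activity",
        "n_events",
        "v1",
        "v2",
        "spontaneous_activity",
        "proportion_consumed_15min",
        "n_hunting_events",
        "mean_hunt_duration_s",
        "bout_frequency_per_min",
        "vigor",
        "basal_ocr",
        "maximal_ocr",
        "nonmito_ocr",
        "fluorescence",
    }
)


def tidy_result_table(rows: list[dict]) -> pd.DataFrame:
    """Build a validated tidy result table (one row per subject x metric)."""
    df = pd.DataFrame(rows, columns=["subject_id", "group_label", "metric_name",
                                     "value", "unit"])
    unknown = set(df["metric_name"]) - METRIC_VOCABULARY
    if unknown:
        raise DataValidationError(f"unregistered metric names: {sorted(unknown)}")
    if df.duplicated(["subject_id", "metric_name"]).any():
        dup = df[df.duplicated(["subject_id", "metric_name"])].iloc[0]
        raise DataValidationError(
            f"duplicate row for subject {dup['subject_id']!r} "
            f"metric {dup['metric_name']!r}"
        )
    return df


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated parse failures
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# Activity CSV


def read_activity_csv(
    path: str | Path, protocol: StimulusProtocol
) -> list[ActivityTrace]:
    """Read a long-format activity CSV into one trace per well.

    Slice indices must be 0-based and contiguous per well and every
    trace must match the protocol length exactly; gaps or length
    mismatches are errors, never silently filled.
    """
    df = _read_csv(path, ["well", "slice_index", "actinteg"])
    if (df["actinteg"] < 0).any():
        row = int(df.index[df["actinteg"] < 0][0])
        raise DataValidationError(f"{path}: negative actinteg at data row {row}")
    traces = []
    for well, sub in df.groupby("well", sort=True):
        idx = sub["slice_index"].to_numpy()
        expected = np.arange(len(idx))
        if not np.array_equal(idx, expected):
            bad = int(np.argmax(idx != expected))
            raise DataValidationError(
                f"{path}: well {well!r}: slice_index gap or disorder at "
                f"position {bad} (found {idx[bad]}, expected {expected[bad]})"
            )
        if len(idx) != protocol.n_slices:
            raise ProtocolMismatchError(
                f"{path}: well {well!r}: {len(idx)} slices but protocol "
                f"requires {protocol.n_slices}"
            )
        traces.append(ActivityTrace(str(well), sub["actinteg"].to_numpy(float),
                                    protocol))
    return traces


def write_activity_csv(path: str | Path, traces: list[ActivityTrace]) -> None:
    frames = [
        pd.DataFrame(
            {
                "well": tr.well_id,
                "slice_index": np.arange(len(tr.values)),
                "actinteg": tr.values,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tracking tables (three files)


def read_tracking_tables(
    counts_path: str | Path,
    convergence_path: str | Path,
    bouts_path: str | Path,
) -> tuple[RotiferCountSeries, EyeConvergenceTrace, BoutIntervals]:
    """Read the three prey-capture tracking tables with validation."""
    cdf = _read_csv(counts_path, ["t", "count"])
    counts = RotiferCountSeries(t=cdf["t"].to_numpy(float),
                                count=cdf["count"].to_numpy(float))
    vdf = _read_csv(convergence_path, ["t", "convergence_deg"])
    conv = EyeConvergenceTrace(t=vdf["t"].to_numpy(float),
                               convergence_deg=vdf["convergence_deg"].to_numpy(float))
    bdf = _read_csv(bouts_path, ["bout_start", "bout_end"])
    bouts = BoutIntervals(bdf[["bout_start", "bout_end"]].to_numpy(float))
    return counts, conv, bouts


def write_tracking_tables(
    counts_path: str | Path,
    convergence_path: str | Path,
    bouts_path: str | Path,
    counts: RotiferCountSeries,
    convergence: EyeConvergenceTrace,
    bouts: BoutIntervals,
) -> None:
    pd.DataFrame({"t": counts.t, "count": counts.count}).to_csv(counts_path,
                                                                index=False)
    pd.DataFrame(
        {"t": convergence.t, "convergence_deg": convergence.convergence_deg}
    ).to_csv(convergence_path, index=False)
    pd.DataFrame(bouts.array, columns=["bout_start", "bout_end"]).to_csv(
        bouts_path, index=False
    )


# ---------------------------------------------------------------------------
# Plate CSV


def read_plate_csv(path: str | Path) -> PlateFluorescence:
    df = _read_csv(path, ["well", "fluorescence"])
    return PlateFluorescence(df)


def write_plate_csv(path: str | Path, plate: PlateFluorescence) -> None:
    plate.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# OCR CSV


def read_ocr_csv(
    path: str | Path, fccp_index: int, raa_index: int
) -> list[OCRTrace]:
    """Read per-well OCR series; injection indices come from the config."""
    df = _read_csv(path, ["well", "t_min", "ocr"])
    traces = []
    for well, sub in df.groupby("well", sort=True):
        traces.append(
            OCRTrace(
                t_min=sub["t_min"].to_numpy(float),
                ocr=sub["ocr"].to_numpy(float),
                fccp_index=fccp_index,
                raa_index=raa_index,
                well_id=str(well),
            )
        )
    return traces


def write_ocr_csv(path: str | Path, traces: list[OCRTrace]) -> None:
    frames = [
        pd.DataFrame({"well": tr.well_id, "t_min": tr.t_min, "ocr": tr.ocr})
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Survival CSV


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["subject", "group", "time", "event"])
    if (df["time"] < 0).any():
        row = int(df.index[df["time"] < 0][0])
        raise DataValidationError(f"{path}: negative time at data row {row}")
    if not df["event"].isin([0, 1]).all():
        row = int(df.index[~df["event"].isin([0, 1])][0])
        raise DataValidationError(f"{path}: event not in {{0,1}} at data row {row}")
    return df


def write_survival_csv(path: str | Path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)
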