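"""Extracellular-flux (Seahorse-style) OCR decomposition.

A respirometry run measures oxygen consumption every 5 minutes through
three phases: baseline, after FCCP (a protonophore uncoupler that
drives the electron transport chain to its maximal rate), and after
rotenone + antimycin A (which block the chain and reveal
nonmitochondrial respiration).

* basal   = mean of the last 3 points before FCCP, minus nonmito
* maximal = max of the points between FCCP and R+AA, minus nonmito
* nonmito = mean of the post-R+AA plateau (the first post-injection
  point is dropped as a transient when at least 3 points are available)

Corrected values below zero are reported, never clamped: a negative
basal or maximal flags an injection problem the caller should see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import OCRTrace
from .errors import DataValidationError


@dataclass(frozen=True)
class OCRSummary:
    """Basal / maximal / nonmitochondrial decomposition of one well."""

    basal: float
    maximal: float
    nonmito: float
    qc_negative: bool  # True when basal or maximal came out below zero


def summarize_ocr(trace: OCRTrace) -> OCRSummary:
    """Decompose an OCR trace into basal, maximal and nonmito components."""
    ocr = trace.ocr
    basal_raw = float(ocr[trace.fccp_index - 3 : trace.fccp_index].mean())
    maximal_raw = float(ocr[trace.fccp_index : trace.raa_index].max())
    tail = ocr[trace.raa_index :]
    if len(tail) >= 3:
        tail = tail[1:]  # drop the post-injection transient
    nonmito = float(tail.mean())
    basal = basal_raw - nonmito
    maximal = maximal_raw - nonmito
    return OCRSummary(
        basal=basal,
        maximal=maximal,
        nonmito=nonmito,
        qc_negative=bool(basal < 0 or maximal < 0),
    )


def cohort_ocr_table(traces_by_group: Mapping[str, Sequence[OCRTrace]]) -> pd.DataFrame:
    """Summarize every well of a cohort into a tidy group-labeled table."""
    if not traces_by_group:
        raise DataValidationError("cohort has no groups")
    rows = []
    for group in sorted(traces_by_group):
        traces = traces_by_group[group]
        if not len(traces):
            raise DataValidationError(f"group {group!r} has no traces")
        for tr in traces:
            s = summarize_ocr(tr)
            rows.append(
                {
                    "well": tr.well_id,
                    "group": group,
                    "basal": s.basal,
                    "maximal": s.maximal,
                    "nonmito": s.nonmito,
                    "qc_negative": s.qc_negative,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["group", "well"], kind="stable")
        .reset_index(drop=True)
    )
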