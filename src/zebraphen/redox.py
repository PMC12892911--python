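"""Noninvasive quartile-based genotype classification from redox fluorescence.

Larvae from a heterozygous in-cross are incubated with resazurin; viable
cells reduce it to fluorescent resorufin, and homozygous mutants with
perturbed succinyl-CoA ligase activity generate a stronger signal.
Wells above the plate's 75th percentile (Q3) are sorted as predicted
homozygous mutants, wells below the 25th percentile (Q1) as predicted
wild type; the middle half is left unassigned.

Percentiles are computed by linear interpolation of order statistics
(the common default in scientific software), and the comparisons are
strict: a well exactly at a threshold stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import PlateFluorescence
from .errors import DataValidationError, InsufficientDataError
from . import simulate as sim

LABELS = ("predicted_hom", "predicted_wt", "unassigned")


@dataclass
class QuartileAssignment:
    """Quartile thresholds plus the resulting per-well labels."""

    q1_threshold: float
    q3_threshold: float
    labels: dict[str, str]  # well_id -> label

    def __post_init__(self) -> None:
        if self.q1_threshold > self.q3_threshold:
            raise DataValidationError("q1_threshold must be <= q3_threshold")

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


def quartile_thresholds(values: np.ndarray) -> tuple[float, float]:
    """25th and 75th percentiles by linear interpolation of order statistics."""
    return (
        float(np.percentile(values, 25, method="linear")),
        float(np.percentile(values, 75, method="linear")),
    )


def classify_plate(plate: PlateFluorescence) -> QuartileAssignment:
    """Label each well by its position relative to the plate quartiles.

    Strictly above Q3 -> ``predicted_hom``; strictly below Q1 ->
    ``predicted_wt``; everything in [Q1, Q3] -> ``unassigned``.
    """
    if len(plate) < 4:
        raise InsufficientDataError(
            f"quartile sorting needs >= 4 wells, got {len(plate)}"
        )
    values = plate.fluorescence
    q1, q3 = quartile_thresholds(values)
    labels = {}
    for well, v in zip(plate.wells, values):
        if v > q3:
            labels[well] = "predicted_hom"
        elif v < q1:
            labels[well] = "predicted_wt"
        else:
            labels[well] = "unassigned"
    return QuartileAssignment(q1_threshold=q1, q3_threshold=q3, labels=labels)


def confusion_metrics(
    assignment: QuartileAssignment, plate: PlateFluorescence
) -> dict:
    """Score a quartile assignment against known genotypes.

    ``false_positive_rate_top`` is the percentage of predicted
    homozygous-mutant wells whose true genotype is wt or het (the
    contamination of the selected pool).  With zero predicted mutants
    the rate is ``None`` (undefined), never 0.
    """
    if "true_genotype" not in plate.df.columns:
        raise DataValidationError("plate has no true_genotype column")
    truth = dict(zip(plate.df["well"], plate.df["true_genotype"]))
    top = [w for w, lab in assignment.labels.items() if lab == "predicted_hom"]
    bottom = [w for w, lab in assignment.labels.items() if lab == "predicted_wt"]
    for w in top:
        if pd.isna(truth.get(w)):
            raise DataValidationError(f"predicted_hom well {w!r} lacks a true genotype")
    n_top = len(top)
    n_fp = sum(1 for w in top if truth[w] in ("wt", "het"))
    fp_rate = None if n_top == 0 else 100.0 * n_fp / n_top
    n_hom_total = int((plate.df["true_genotype"] == "hom").sum())
    n_hom_missed = n_hom_total - sum(1 for w in top if truth[w] == "hom")
    fn_rate = None if n_hom_total == 0 else 100.0 * n_hom_missed / n_hom_total
    composition = {
        lab: {
            g: sum(
                1
                for w, l in assignment.labels.items()
                if l == lab and truth.get(w) == g
            )
            for g in ("wt", "het", "hom")
        }
        for lab in LABELS
    }
    return {
        "false_positive_rate_top": fp_rate,
        "false_negative_rate": fn_rate,
        "yield_top": n_top,
        "n_false_positive_top": n_fp,
        "yield_bottom": len(bottom),
        "composition": composition,
    }


def sorting_power_curve(
    separations: Sequence[float],
    sds: Sequence[float],
    plate_sizes: Sequence[int] = (94,),
    n_replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo false-positive rate of the sorter over a parameter grid.

    ``separation`` is the hom-vs-wt mean fluorescence difference (wt and
    het share mean 1.0); ``sd`` applies to all genotypes.  Returns one
    row per (separation, sd, plate size) cell with the pooled FP rate
    and a normal-approximation 95% CI.
    """
    if n_replicates < 1:
        raise DataValidationError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for sep in separations:
        for sd in sds:
            for n in plate_sizes:
                child = ss.spawn(1)[0]
                plate_seeds = child.generate_state(n_replicates) % (2**31)
                n_fp = n_top = 0
                for ps in plate_seeds:
                    plate = sim.simulate_plate(
                        n_wells=n,
                        mu_by_genotype={"wt": 1.0, "het": 1.0, "hom": 1.0 + sep},
                        sd_by_genotype={"wt": sd, "het": sd, "hom": sd},
                        seed=int(ps),
                    )
                    m = confusion_metrics(classify_plate(plate), plate)
                    n_top += m["yield_top"]
                    n_fp += m["n_false_positive_top"]
                rate = None if n_top == 0 else 100.0 * n_fp / n_top
                if rate is None:
                    lo = hi = None
                else:
                    p = n_fp / n_top
                    half = 196.0 * np.sqrt(p * (1 - p) / n_top)
                    lo, hi = max(rate - half, 0.0), min(rate + half, 100.0)
                rows.append(
                    {
                        "separation": sep,
                        "sd": sd,
                        "plate_size": n,
                        "fp_rate_pct": rate,
                        "ci_lo": lo,
                        "ci_hi": hi,
                        "n_predicted_hom": n_top,
                    }
                )
    return pd.DataFrame(rows)
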