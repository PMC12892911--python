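"""Statistical layer: the study's named group-comparison procedures.

Omnibus tests (Kruskal-Wallis, one-way ANOVA) pair with their post hoc
procedures (Dunn with Bonferroni adjustment, Tukey HSD); two-group and
categorical comparisons use Mann-Whitney U and Fisher's exact test; and
survival is summarized with Kaplan-Meier curves plus pairwise log-rank
tests under Bonferroni correction.

Standard tests are delegated to scipy / statsmodels / lifelines; the
Dunn post hoc z-tests are computed here (midranks with tie correction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DataValidationError, InsufficientDataError


@dataclass
class GroupComparison:
    """Omnibus test result with a pairwise post hoc table."""

    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group_i, group_j, p_raw, p_adjusted, method


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for k, v in out.items():
        if len(v) == 0:
            raise InsufficientDataError(f"group {k!r} is empty")
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> GroupComparison:
    """Kruskal-Wallis H test with Dunn's pairwise post hoc z-tests.

    Midranks handle ties and the H statistic carries the usual tie
    correction.  Dunn's pairwise z uses the pooled-rank variance with
    tie correction; pairwise p-values are Bonferroni-adjusted by the
    number of comparisons (the default; "none" disables adjustment).
    """
    g = _as_groups(groups)
    names = sorted(g)
    pooled = np.concatenate([g[k] for k in names])
    n_tot = len(pooled)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*[g[k] for k in names])

    ranks = sps.rankdata(pooled)  # midranks
    offsets = np.cumsum([0] + [len(g[k]) for k in names])
    mean_rank = {
        k: float(ranks[offsets[i] : offsets[i + 1]].mean())
        for i, k in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0
    if n_tot > 1:
        var_base -= tie_term / (12.0 * (n_tot - 1))

    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(g[a]) + 1.0 / len(g[b])))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = bonferroni(p_raw, m) if adjust == "bonferroni" else p_raw
        rows.append(
            {"group_i": a, "group_j": b, "statistic": z, "p_raw": p_raw,
             "p_adjusted": p_adj, "method": f"dunn+{adjust}"}
        )
    return GroupComparison("kruskal-wallis", float(h), float(p), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Ordinary one-way ANOVA with Tukey's HSD pairwise comparisons."""
    g = _as_groups(groups)
    names = sorted(g)
    for k, v in g.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {k!r} needs >= 2 observations")
    samples = [g[k] for k in names]
    pooled = np.concatenate(samples)
    within_var = sum(np.var(s, ddof=1) for s in samples)
    if within_var == 0 and np.all(pooled == pooled[0]):
        f_stat, p = 0.0, 1.0
        rows = [
            {"group_i": a, "group_j": b, "statistic": 0.0, "p_raw": 1.0,
             "p_adjusted": 1.0, "method": "tukey-hsd"}
            for a, b in itertools.combinations(names, 2)
        ]
        return GroupComparison("anova", f_stat, p, pd.DataFrame(rows))
    f_stat, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_i": names[i],
                "group_j": names[j],
                "statistic": float(hsd.statistic[i, j]),
                "p_raw": float(hsd.pvalue[i, j]),
                "p_adjusted": float(hsd.pvalue[i, j]),  # HSD is family-wise already
                "method": "tukey-hsd",
            }
        )
    return GroupComparison("anova", float(f_stat), float(p), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Conditional odds ratio and two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables (at
    fixed margins) no more probable than the observed one.  A zero
    margin makes the table degenerate: p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DataValidationError("table must be a non-negative 2x2 integer table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    odds = float(sps.contingency.odds_ratio(t, kind="conditional").statistic)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


# ---------------------------------------------------------------------------
# Mann-Whitney U


#: Combined sample size at or below which the exact U distribution is used.
MWU_EXACT_MAX_N = 20


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact U distribution when the combined sample size is at
    most 20 and there are no ties, and the normal approximation with
    tie and continuity corrections otherwise.  Returns (U for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= MWU_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Kaplan-Meier + pairwise log-rank


def km_logrank(
    records: pd.DataFrame,
    pairwise: bool = True,
    adjust: str = "bonferroni",
    horizon: Optional[float] = None,
) -> dict:
    """Kaplan-Meier survival by group with pairwise log-rank tests.

    ``records`` must have columns ``group``, ``time`` and ``event``
    (1 = death, 0 = censored).  Pairwise log-rank p-values are
    Bonferroni-adjusted over the number of pairs.  With no events
    anywhere, all curves are 1 and the log-rank p-values are ``None``
    (undefined), never fabricated.  ``horizon`` adds the estimated
    proportion alive at that time per group.
    """
    for col in ("group", "time", "event"):
        if col not in records.columns:
            raise DataValidationError(f"survival records missing column {col!r}")
    if (records["time"] < 0).any():
        raise DataValidationError("negative survival time")
    if not records["event"].isin([0, 1]).all():
        raise DataValidationError("event must be 0 or 1")
    names = sorted(records["group"].unique())
    if len(names) < 2:
        raise InsufficientDataError("need >= 2 groups for survival comparison")
    curves = {}
    fitters = {}
    for gname in names:
        sub = records[records["group"] == gname]
        if len(sub) == 0:
            raise DataValidationError(f"group {gname!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=gname)
        fitters[gname] = kmf
        curves[gname] = kmf.survival_function_.rename(
            columns={gname: "survival"}
        ).reset_index(names="time")

    any_event = bool((records["event"] == 1).any())
    rows = []
    if pairwise:
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        for a, b in pairs:
            sa = records[records["group"] == a]
            sb = records[records["group"] == b]
            if not any_event or (
                (sa["event"] == 0).all() and (sb["event"] == 0).all()
            ):
                rows.append({"group_i": a, "group_j": b, "statistic": None,
                             "p_raw": None, "p_adjusted": None,
                             "method": f"logrank+{adjust}"})
                continue
            res = logrank_test(sa["time"], sb["time"],
                               event_observed_A=sa["event"],
                               event_observed_B=sb["event"])
            p_raw = float(res.p_value)
            p_adj = bonferroni(p_raw, m) if adjust == "bonferroni" else p_raw
            rows.append({"group_i": a, "group_j": b,
                         "statistic": float(res.test_statistic),
                         "p_raw": p_raw, "p_adjusted": p_adj,
                         "method": f"logrank+{adjust}"})
    out = {
        "curves": curves,
        "pairwise": pd.DataFrame(rows),
        "any_event": any_event,
    }
    if horizon is not None:
        out["alive_at_horizon"] = {
            gname: float(fitters[gname].predict(horizon)) for gname in names
        }
    return out


# ---------------------------------------------------------------------------
# Box-plot summary convention


def boxplot_stats(values: Sequence[float]) -> dict:
    """Box-plot elements: median, quartile box, 1.5x-IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise InsufficientDataError("no observations")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
    }
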