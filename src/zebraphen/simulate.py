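"""Synthetic-data generators with machine-readable ground truth.

Every rig output the pipeline consumes can be simulated here with known
truth, so each detector and summary can be scored without any recorded
data.  All generators are pure functions of (parameters, seed): a single
seed is split into independent per-component streams via
``numpy.random.SeedSequence.spawn``, so adding one sub-generator never
perturbs another's draws.

The defaults describe a heterozygous in-cross screened on a 94-well
plate (Mendelian 1:2:1 wt:het:hom), with homozygous mutants producing a
clearly elevated but imperfectly separated redox-fluorescence signal,
hypoactive flash responses, Poisson hunting events depleting a rotifer
arena, three-plateau respirometry traces, and group-specific exponential
survival hazards observed on a twice-daily grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    SLICES_PER_SECOND,
    ActivityTrace,
    BoutIntervals,
    EyeConvergenceTrace,
    HuntingEvent,
    OCRTrace,
    PlateFluorescence,
    RotiferCountSeries,
    StimulusProtocol,
)
from .errors import DataValidationError

# Default redox-fluorescence mixture for a heterozygous in-cross, in
# plate-reader units normalized to the wt mean.  Homozygous mutants show
# a ~1.8-fold elevated resorufin signal with larger spread; wt and het
# wells are indistinguishable (carriers are phenotypically silent).
DEFAULT_MU = {"wt": 1.0, "het": 1.0, "hom": 1.8}
DEFAULT_SD = {"wt": 0.15, "het": 0.15, "hom": 0.25}


@dataclass(frozen=True)
class GenotypeEffect:
    """Behavioral parameters of one genotype for activity simulation.

    ``flash_response_prob`` is the probability of responding within 4 s
    of flash 1; flash k responds with probability
    ``flash_response_prob * fatigue**(k-1)``.
    """

    label: str = "wt"
    bout_rate_hz: float = 0.5
    flash_response_prob: float = 0.9
    response_amp_mean: float = 20.0
    response_amp_sd: float = 4.0
    fatigue: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flash_response_prob <= 1.0:
            raise DataValidationError("flash_response_prob must be in [0, 1]")
        if self.bout_rate_hz < 0:
            raise DataValidationError("bout_rate_hz must be >= 0")
        if not 0.0 < self.fatigue <= 1.0:
            raise DataValidationError("fatigue must be in (0, 1]")


@dataclass
class TruthBout:
    """Ground truth for one simulated activity pulse."""

    onset_slice: int
    duration_slices: int
    amplitude: float
    kind: str  # "spontaneous" or "flash"


@dataclass
class PreySessionTruth:
    """Ground truth of a simulated prey-capture session."""

    true_events: list[HuntingEvent]
    capture_times: list[float]
    initial_rotifers: int


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Plate fluorescence


def simulate_plate(
    n_wells: int = 94,
    mendelian_probs: Sequence[float] = (0.25, 0.5, 0.25),
    mu_by_genotype: Optional[dict[str, float]] = None,
    sd_by_genotype: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> PlateFluorescence:
    """Simulate a fluorescence plate from a heterozygous in-cross.

    Genotypes are drawn multinomially (wt, het, hom) and each well's
    fluorescence from the genotype's normal distribution.  True
    genotypes are attached for downstream scoring.
    """
    if n_wells < 4:
        raise DataValidationError(
            f"n_wells must be >= 4 for quartile sorting, got {n_wells}"
        )
    probs = np.asarray(mendelian_probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise DataValidationError("mendelian_probs must be 3 probabilities summing to 1")
    mu = dict(DEFAULT_MU if mu_by_genotype is None else mu_by_genotype)
    sd = dict(DEFAULT_SD if sd_by_genotype is None else sd_by_genotype)
    if any(sd[g] < 0 for g in ("wt", "het", "hom")):
        raise DataValidationError("sds must be >= 0")
    rng = np.random.default_rng(seed)
    genotypes = rng.choice(["wt", "het", "hom"], size=n_wells, p=probs)
    fluor = np.array(
        [rng.normal(mu[g], sd[g]) if sd[g] > 0 else mu[g] for g in genotypes]
    )
    df = pd.DataFrame(
        {
            "well": [f"W{i + 1:03d}" for i in range(n_wells)],
            "fluorescence": fluor,
            "true_genotype": genotypes,
        }
    )
    return PlateFluorescence(df)


# ---------------------------------------------------------------------------
# Activity (actinteg) traces


def _truncnorm_amp(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_actinteg(
    protocol: StimulusProtocol,
    effect: GenotypeEffect,
    n_larvae: int = 1,
    seed: int = 0,
) -> tuple[list[ActivityTrace], list[list[TruthBout]]]:
    """Simulate actinteg traces with bout-level ground truth.

    Spontaneous bouts arrive as a homogeneous Poisson process at
    ``effect.bout_rate_hz`` over the whole protocol.  Each light flash k
    elicits, with probability ``flash_response_prob * fatigue**(k-1)``,
    one response bout with latency uniform in [0, 4) s.  Every bout
    deposits a rectangular pulse of 2-5 slices with truncated-normal
    amplitude; overlapping pulses sum.
    """
    if n_larvae < 1:
        raise DataValidationError("n_larvae must be >= 1")
    n_slices = protocol.n_slices
    duration = protocol.duration_s
    flash_onsets = protocol.flash_onsets_s()
    rngs = _streams(seed, n_larvae)
    traces, truths = [], []
    for i, rng in enumerate(rngs):
        bouts: list[TruthBout] = []
        # spontaneous point process
        if effect.bout_rate_hz > 0:
            n_spont = rng.poisson(effect.bout_rate_hz * duration)
            onsets = np.sort(rng.uniform(0.0, duration, size=n_spont))
        else:
            onsets = np.empty(0)
        onset_slices = np.floor(onsets * SLICES_PER_SECOND).astype(int)
        durs = rng.integers(2, 6, size=len(onset_slices))
        amps = _truncnorm_amp(rng, effect.response_amp_mean, effect.response_amp_sd,
                              len(onset_slices))
        for s, d, a in zip(onset_slices, durs, amps):
            bouts.append(TruthBout(int(s), int(d), float(a), "spontaneous"))
        # stimulus-locked responses
        for k, t_flash in enumerate(flash_onsets, start=1):
            p = effect.flash_response_prob * effect.fatigue ** (k - 1)
            if rng.uniform() < p:
                latency = rng.uniform(0.0, 4.0)
                s = int(np.floor((t_flash + latency) * SLICES_PER_SECOND))
                d = int(rng.integers(2, 6))
                a = float(_truncnorm_amp(rng, effect.response_amp_mean,
                                         effect.response_amp_sd, 1)[0])
                bouts.append(TruthBout(s, d, a, "flash"))
        values = np.zeros(n_slices)
        for b in bouts:
            end = min(b.onset_slice + b.duration_slices, n_slices)
            if b.onset_slice < n_slices:
                values[b.onset_slice:end] += b.amplitude
        bouts.sort(key=lambda b: b.onset_slice)
        traces.append(ActivityTrace(f"L{i + 1:03d}", values, protocol))
        truths.append(bouts)
    return traces, truths


# ---------------------------------------------------------------------------
# Prey-capture sessions


def simulate_prey_session(
    duration_s: float = 900.0,
    initial_rotifers: int = 50,
    hunt_rate_hz: float = 0.02,
    hunt_success_prob: float = 0.6,
    event_bout_range: tuple[int, int] = (1, 6),
    count_noise: float = 0.01,
    background_bout_rate_hz: float = 0.5,
    frame_rate: float = 15.0,
    seed: int = 0,
) -> tuple[RotiferCountSeries, EyeConvergenceTrace, BoutIntervals, PreySessionTruth]:
    """Simulate one larva hunting rotifers in an open arena.

    Hunting events arrive as a Poisson process at ``hunt_rate_hz``; each
    event is 1-6 consecutive bouts during which eye convergence sits
    above 60 deg, rising during the first bout and releasing after the
    last.  A successful event (Bernoulli ``hunt_success_prob``)
    decrements the rotifer count at event end.  Observed counts are the
    true counts plus injected single-frame dropout spikes at rate
    ``count_noise`` per frame, exercising the median filter.
    Non-hunting bouts occur at ``background_bout_rate_hz`` with
    convergence below threshold.
    """
    if initial_rotifers < 1:
        raise DataValidationError("initial_rotifers must be >= 1")
    rng_ev, rng_bg, rng_noise = _streams(seed, 3)

    bout_dur, bout_gap = 0.25, 0.15  # s; typical larval bout cadence
    lo, hi = event_bout_range

    # hunting events: Poisson arrivals, thinned to non-overlapping
    n_arr = rng_ev.poisson(hunt_rate_hz * duration_s)
    arrivals = np.sort(rng_ev.uniform(0.0, duration_s, size=n_arr))
    events: list[tuple[float, float, int, bool]] = []  # start, end, n_bouts, success
    last_end = -np.inf
    for t0 in arrivals:
        nb = int(rng_ev.integers(lo, hi + 1))
        span = nb * bout_dur + (nb - 1) * bout_gap
        if t0 <= last_end + 1.0 or t0 + span >= duration_s - 1.0:
            continue  # keep events separated and inside the session
        success = bool(rng_ev.uniform() < hunt_success_prob)
        events.append((t0, t0 + span, nb, success))
        last_end = t0 + span

    event_bouts: list[tuple[float, float]] = []
    for t0, _, nb, _ in events:
        t = t0
        for _ in range(nb):
            event_bouts.append((t, t + bout_dur))
            t += bout_dur + bout_gap

    # background (non-hunting) bouts, avoiding event spans
    n_bg = rng_bg.poisson(background_bout_rate_hz * duration_s)
    bg_starts = np.sort(rng_bg.uniform(0.0, duration_s - bout_dur, size=n_bg))
    bg_bouts = []
    for s in bg_starts:
        e = s + bout_dur
        clear = all(e <= es - 0.5 or s >= ee + 0.5 for es, ee, _, _ in events)
        prev = bg_bouts[-1] if bg_bouts else None
        if clear and (prev is None or s >= prev[1] + 0.05):
            bg_bouts.append((s, e))
    all_bouts = BoutIntervals(sorted(event_bouts + bg_bouts))

    # convergence trace: high from just after the first bout's onset
    # until just after the last bout's end of each event
    t = np.arange(0.0, duration_s, 1.0 / frame_rate)
    conv = 25.0 + rng_noise.normal(0.0, 3.0, size=len(t))
    dt = 1.0 / frame_rate
    for t0, t1, _, _ in events:
        hi_mask = (t > t0 + 0.5 * dt) & (t <= t1 + 0.5 * dt)
        conv[hi_mask] = 75.0 + rng_noise.normal(0.0, 2.0, size=int(hi_mask.sum()))
    conv = np.clip(conv, 0.0, 110.0)

    # rotifer counts: captures at successful event ends
    capture_times = sorted(t1 for _, t1, _, ok in events if ok)
    true_count = np.full(len(t), float(initial_rotifers))
    for ct in capture_times:
        true_count[t >= ct] -= 1.0
    true_count = np.maximum(true_count, 0.0)
    observed = true_count.copy()
    candidates = np.flatnonzero(rng_noise.uniform(size=len(t)) < count_noise)
    drop = rng_noise.integers(1, 4, size=len(t)).astype(float)
    # dropouts are strictly single-frame: never allow two adjacent spikes,
    # so a centered median over many frames is guaranteed to remove them
    last = -2
    for i in candidates:
        if i - last > 1:
            observed[i] = max(observed[i] - drop[i], 0.0)
            last = i

    truth = PreySessionTruth(
        true_events=[
            HuntingEvent(start_s=t0, end_s=t1, n_bouts=nb) for t0, t1, nb, _ in events
        ],
        capture_times=[float(c) for c in capture_times],
        initial_rotifers=initial_rotifers,
    )
    counts = RotiferCountSeries(t=t, count=observed)
    convergence = EyeConvergenceTrace(t=t, convergence_deg=conv)
    return counts, convergence, all_bouts, truth


# ---------------------------------------------------------------------------
# Tail-angle traces


def simulate_tail_trace(
    duration_s: float = 60.0,
    bout_rate_hz: float = 0.5,
    bout_amp_deg: float = 30.0,
    bout_dur_ms: float = 200.0,
    noise_sd_deg: float = 0.5,
    frame_rate: float = 700.0,
    tail_beat_hz: float = 20.0,
    seed: int = 0,
    bout_starts_s: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray, BoutIntervals, np.ndarray]:
    """Simulate a tail-angle trace of damped-sinusoid bouts on noise.

    Returns ``(t, angle_deg, truth_intervals, truth_vigor)`` where
    ``truth_vigor`` is the RMS angular velocity (deg/s) of each injected
    bout waveform.  ``bout_starts_s`` overrides the Poisson arrivals
    with explicit onsets (for deterministic fixtures).
    """
    if frame_rate <= 0:
        raise DataValidationError("frame_rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate))
    t = np.arange(n) / frame_rate
    angle = rng.normal(0.0, noise_sd_deg, size=n) if noise_sd_deg > 0 else np.zeros(n)

    dur = bout_dur_ms / 1000.0
    if bout_starts_s is None:
        n_bouts = rng.poisson(bout_rate_hz * duration_s) if bout_rate_hz > 0 else 0
        starts = np.sort(rng.uniform(0.0, max(duration_s - dur, 0.0), size=n_bouts))
        # enforce a refractory gap so truth intervals never overlap
        keep, last = [], -np.inf
        for s in starts:
            if s >= last + dur + 0.05:
                keep.append(s)
                last = s
        starts = np.array(keep)
    else:
        starts = np.asarray(bout_starts_s, dtype=float)

    intervals, vigors = [], []
    tau = dur / 2.0
    for s in starts:
        i0 = int(round(s * frame_rate))
        i1 = min(i0 + int(round(dur * frame_rate)), n)
        tt = (np.arange(i0, i1) - i0) / frame_rate
        wave = bout_amp_deg * np.exp(-tt / tau) * np.sin(2 * np.pi * tail_beat_hz * tt)
        angle[i0:i1] += wave
        # truth vigor: RMS of the waveform's analytic derivative
        dwave = bout_amp_deg * np.exp(-tt / tau) * (
            2 * np.pi * tail_beat_hz * np.cos(2 * np.pi * tail_beat_hz * tt)
            - np.sin(2 * np.pi * tail_beat_hz * tt) / tau
        )
        vigors.append(float(np.sqrt(np.mean(dwave**2))))
        intervals.append((i0 / frame_rate, i1 / frame_rate))
    return t, angle, BoutIntervals(intervals), np.asarray(vigors)


# ---------------------------------------------------------------------------
# OCR traces


def simulate_ocr(
    basal_true: float = 50.0,
    max_true: float = 120.0,
    nonmito_true: float = 10.0,
    n_points_per_phase: tuple[int, int, int] = (5, 4, 4),
    noise_sd: float = 0.0,
    seed: int = 0,
    well_id: str = "w1",
) -> OCRTrace:
    """Simulate a three-plateau respirometry trace at 5-min cadence.

    Pre-FCCP points sit at ``basal_true + nonmito_true``; post-FCCP
    points at ``max_true + nonmito_true`` (the uncoupled peak); post
    rotenone/antimycin-A points at ``nonmito_true``; additive Gaussian
    noise on every point.
    """
    if not (max_true >= basal_true >= nonmito_true >= 0):
        raise DataValidationError(
            "require max_true >= basal_true >= nonmito_true >= 0, got "
            f"({max_true}, {basal_true}, {nonmito_true})"
        )
    n1, n2, n3 = n_points_per_phase
    rng = np.random.default_rng(seed)
    levels = np.concatenate(
        [
            np.full(n1, basal_true + nonmito_true),
            np.full(n2, max_true + nonmito_true),
            np.full(n3, nonmito_true),
        ]
    )
    if noise_sd > 0:
        levels = levels + rng.normal(0.0, noise_sd, size=len(levels))
    t_min = 5.0 * np.arange(len(levels))
    return OCRTrace(t_min=t_min, ocr=levels, fccp_index=n1, raa_index=n1 + n2,
                    well_id=well_id)


# ---------------------------------------------------------------------------
# Survival records


def simulate_survival(
    group_hazards: dict[str, float],
    n_per_group: int = 24,
    censor_time: float = 9.0,
    seed: int = 0,
    grid_per_day: int = 2,
) -> pd.DataFrame:
    """Simulate survival with exponential hazards and twice-daily checks.

    Event times are exponential per group hazard (events per day),
    administratively censored at ``censor_time`` days, and rounded up to
    the next observation on a ``grid_per_day``-per-day monitoring grid
    (a fish dying between checks is recorded at the following check).
    Returns a tidy frame with columns subject, group, time, event.
    """
    if any(h < 0 for h in group_hazards.values()):
        raise DataValidationError("hazards must be >= 0")
    rngs = _streams(seed, len(group_hazards))
    rows = []
    for (group, hazard), rng in zip(sorted(group_hazards.items()), rngs):
        if hazard > 0:
            times = rng.exponential(1.0 / hazard, size=n_per_group)
        else:
            times = np.full(n_per_group, np.inf)
        for i, tdeath in enumerate(times):
            if tdeath >= censor_time:
                t_obs, event = censor_time, 0
            else:
                t_obs = np.ceil(tdeath * grid_per_day) / grid_per_day
                t_obs, event = min(t_obs, censor_time), 1
            rows.append(
                {"subject": f"{group}_{i + 1:03d}", "group": group,
                 "time": float(t_obs), "event": event}
            )
    return pd.DataFrame(rows)
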