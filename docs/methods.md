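# Methods

This note records the models, conventions and numerical choices behind
each pipeline stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Time base and intervals

Activity recorders report "actinteg" — the summed pixel change per
acquisition slice of exactly 1/15 s. The slice duration is carried as
the rational 1/15 (never a rounded float), and slice indices are
integers, so a 1140-s protocol maps to exactly 17,100 slices with no
cumulative drift. All other times are float seconds. Every interval in
the package (bouts, hunting events, analysis bins) is half-open
`[start, end)`, which makes binning into 5-min intervals unambiguous.

Two stimulus protocols are built in: *simple* (300 s dark + 10 s
light; the response is scored over the first 4 s of light only, because
larvae subsequently freeze) and *extended* (300 s dark adaptation,
600 s spontaneous window, then 8 cycles of 1 s light + 29 s dark).

## Quartile genotype sorting

Fluorescence percentiles use linear interpolation between order
statistics — the default convention of mainstream scientific software —
and the choice is isolated in `redox.quartile_thresholds` so it can be
swapped; a rank-based brute-force oracle test pins the convention.
Threshold comparisons are strict: a well exactly at Q1 or Q3 stays
unassigned. This is the conservative reading of sorting "above"/"under"
the quartiles and avoids asymmetric tie-breaking; its corollary (an
all-equal plate assigns nothing) is tested. Quartiles are computed per
plate, not pooled across plates.

The false-positive rate is the contamination of the selected pool:
100 × (predicted mutants that are truly wt or het) / (predicted
mutants). A zero denominator yields an undefined marker, never 0.

A structural property of this design worth knowing: with genotypes
drawn multinomially 1:2:1, the number of true homozygotes on a 94-well
plate is Bin(94, 0.25) (mean 23.5) while strict-above-Q3 selection
takes 24 wells whenever fluorescence values are distinct. Every
shortfall well is a false positive regardless of how well the
fluorescence separates, so the pooled FP rate over many plates has a
floor of E[max(0, 24 − n_hom)]/24 ≈ 8.1% that no mixture parameters can
beat; `redox.sorting_power_curve` shows the measured rate flattening at
that floor as separation grows. A single favorable plate can still come
in lower (e.g. 1 contaminant among 24, 4.2%). Screening workflows that
need a lower pooled contamination must either verify selected wells
(e.g. by HRM genotyping, as done in practice) or select fewer wells
than the expected mutant count.

## Synthetic generators

All generators are pure functions of (parameters, seed). A single seed
is split into independent per-component streams with
`numpy.random.SeedSequence.spawn`, so adding a component never perturbs
another's draws. Defaults describe the study conditions; where a value
is only known qualitatively, a realistic choice is documented here.

* **Plates** — genotypes multinomial (0.25, 0.5, 0.25); fluorescence
  normal per genotype. Defaults (wt/het N(1.0, 0.15), hom N(1.8, 0.25),
  in units normalized to the wt mean) give clear but imperfect
  separation: homozygous signals overlap the carrier distribution in
  the tails, as plate readers show in practice.
* **Activity traces** — spontaneous bouts as a homogeneous Poisson
  process (default 0.5 bouts/s); flash k elicits a response with
  probability p·fatigue^(k−1) and latency uniform in [0, 4) s. Each
  bout deposits a rectangular pulse of 2–5 slices with truncated-normal
  amplitude (default 20 ± 4 actinteg); overlapping pulses sum. Pulses
  are rectangular rather than kinematically shaped because every LFR
  metric depends only on amplitude and occupancy — simple pulses make
  the ground truth exact.
* **Prey sessions** — hunting events arrive as a Poisson process
  (default 0.02 events/s against 50 rotifers over 900 s), are thinned
  to be non-overlapping, and comprise 1–6 consecutive bouts (250 ms
  bout, 150 ms gap). Convergence rises above 60° just after the first
  bout's onset and releases after the last bout's end, matching the
  detector's bout-aligned semantics exactly, so clean recovery is exact
  by construction. Successful events (default probability 0.6)
  decrement the count at event end. Count dropouts are strictly
  single-frame (adjacent spikes are suppressed), which a 10-s centered
  median removes by construction — that is the property the filter
  exists to provide.
* **Tail traces** — bouts are damped sinusoids (default 30° amplitude,
  20 Hz beat, 200 ms duration) on Gaussian baseline noise at a
  configurable frame rate (default 700 frames/s; the rig's rate is not
  fixed by the assay, so it is a parameter, not a constant). Bout
  arrivals are Poisson thinned by a non-paralyzable refractory dead
  time (bout duration + 50 ms), so the observed bout rate is
  λ/(1 + λτ); tests use that corrected expectation. Truth vigor is the
  RMS of the waveform's analytic derivative.
* **OCR traces** — three plateaus at basal+nonmito, maximal+nonmito and
  nonmito with additive Gaussian noise, 5-min cadence, injections
  marked after plateaus 1 and 2.
* **Survival** — exponential event times per group hazard,
  administrative censoring, and discretization to a twice-daily
  observation grid (a death between checks is recorded at the next
  check).

What the generators do **not** emulate: video-level artifacts
(occlusion, tracking loss), non-stationary behavioral states
(satiation, circadian drift), correlated noise across wells, instrument
drift in respirometry, or interval-censoring ambiguity in survival.
Passing recovery tests therefore demonstrates correctness of the
computations, not robustness to every artifact of real recordings.

## Event detection and LFR conventions

A movement event is a maximal run of slices at or above an activity
threshold; runs separated by at most `merge_gap_slices` sub-threshold
slices merge. Recorders do not expose their internal detection
threshold, so the threshold is an explicit analysis parameter; the
documented default is 3× the median nonzero dark-epoch slice value, and
correctness is pinned by ground-truth recovery tests rather than a
magic constant. "Maximal amplitude" is the per-slice maximum (actinteg
is already a per-slice aggregate; no envelope smoothing).

V1/V2 report mean actinteg per second over [onset, onset+2 s) and
[onset+2 s, onset+30 s); the 1-s light pulse is inside V1's window.
Per-flash values are averaged across the 8 flashes with equal weight,
then across individuals at the reporting layer; with equal window
lengths this equals the pooled single-pass mean (tested as an
identity). The spontaneous window is the extended protocol's second
dark epoch; the first 300 s of adaptation are excluded.

## Prey capture

The rolling median is centered, `[t − w/2, t + w/2]`, truncated at the
series edges (no padding, so early depletion is not biased by invented
values); a relative 1e-9 tolerance keeps samples lying exactly on a
window boundary inside the window on regular float time grids. Output
medians of integer counts may be half-integers where a window holds an
even number of samples. The depletion baseline is the mean filtered
count over the first 60 s; proportions are not clamped — negative
values are reported with a QC flag since they indicate baseline or
tracking problems.

Hunting-event semantics: a bout is *converging* when convergence at its
onset is at or below threshold but rises above during the bout, and
*still-converged* when the onset sample is already above threshold. An
event runs from a converging bout through the maximal run of
immediately following still-converged bouts. "Converged at bout onset"
operationalizes the convention that an event ends with the last bout
*before which* the eyes are still converged; the rule is pinned by
tests. Interval summaries assign each event to the 5-min bin containing
its start; empty bins report an undefined mean duration, not zero.

## Kinematics

Bout segmentation smooths |dθ/dt| with a 15-ms moving average and
applies hysteresis (open above `on`, close below `off`); bouts shorter
than 40 ms are dropped and gaps shorter than 20 ms merged. Data-driven
default thresholds (median + 5×MAD / + 2×MAD of the smoothed speed) are
conventions, not measurements. Vigor = RMS of the raw angular velocity
within the bout — the simplest monotone intensity proxy, pinned by the
sinusoid closed form A·2πf/√2 (within 1%, the residual being the
finite-difference attenuation of the derivative at 700 frames/s).

Bootstrap bands (95% for vigor densities, 99% for the mobility
timecourse) resample at the individual level only; bouts within a larva
are not independent, so per-bout resampling is never used (asserted in
tests). The divergence mask marks bins where the two groups' bands are
disjoint. Both groups restart the bootstrap stream at the same seed —
a paired bootstrap — which makes the mask exactly symmetric under
swapping group order. "Mobility" is implemented as the bout-occupancy
fraction per time bin; this is a convention, as the underlying
trajectory measure is not uniquely determined by the assay.

## Bioenergetics

Basal uses exactly the last 3 pre-FCCP points; maximal is the maximum
over the whole FCCP-to-R+AA window (the instrument may take several
measurements there, and the uncoupled peak need not be the first). The
nonmitochondrial level is the mean of the post-R+AA plateau, dropping
the first post-injection point as a transient when at least three are
available — a plateau mean is less noise-sensitive than any single
point, and the choice is isolated in one function. Negative corrected
values are reported with a QC flag, never clamped: clamping would hide
injection failures.

## Statistics

Standard procedures are delegated: scipy for Kruskal–Wallis, ANOVA,
Tukey HSD, Fisher's exact (conditional odds ratio) and Mann–Whitney;
lifelines for Kaplan–Meier and log-rank. Dunn's pairwise z-tests are
implemented here (midranks, tie-corrected pooled variance, Bonferroni
adjustment by default). Test correctness is pinned against independent
brute-force oracles: full rank enumeration for Mann–Whitney,
hypergeometric enumeration for Fisher, an exact permutation
distribution for the Kruskal–Wallis p at n = 8, hand-computed
product-limit values for Kaplan–Meier, and rank-based percentiles for
the box-plot convention (median, quartile box, 1.5×IQR whiskers,
outliers as points).

The Mann–Whitney implementation switches from the exact distribution to
the tie- and continuity-corrected normal approximation above a combined
sample size of 20 (or whenever ties are present); both branches are
oracle-tested. Survival times observed on the twice-daily grid are
treated as exact at the observation time; no interval-censoring model
is fit. Under matched exponential hazards the log-rank p-value remains
null-uniform despite the heavy ties this grid induces (checked by a KS
test over 500 simulated cohorts).

## Problem sizes used in the test suite

Monte-Carlo checks use cohorts large enough for 3-SE assertions while
keeping the default suite fast: 200–500 simulated larvae for
point-process means, 100 seeds for detector ground-truth recovery,
500 cohorts for the log-rank calibration, 100 matched-group runs at the
open-arena cohort sizes (10 and 17 larvae) for the divergence-mask
null rate, and 200 plates of 94 wells for the sorter benchmark.

## Known limitations

* The pipeline starts at derived traces and counts; raw-video
  processing (background models, rotifer segmentation, eye tracking) is
  out of scope, as is the published multi-category bout classifier —
  only the simplified segmentation above is provided, with an optional
  pass-through label column.
* The quartile sorter's pooled false-positive floor under Mendelian
  sampling (≈8% at 94 wells; see above) is a property of the selection
  rule, not of the dye or the reader.
* Generator effect sizes for behavioral differences are free,
  documented parameters; cohort-level group comparisons in the tests
  verify sign and power under those parameters, not published effect
  magnitudes, which are available only graphically.
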