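# Methods

## The cumulative-labeling model

An asynchronous population with growth fraction GF cycles with period Tc
(S-phase Ts, combined G2+M duration Tg2m, phase order G1→S→G2→M, S occupying
[Tc − Ts − Tg2m, Tc − Tg2m] within the cycle). Under continuous label
exposure starting at t = 0, a cycling cell becomes label-positive as soon as
it spends any time in S. For cells with a common cycle length and uniformly
distributed cycle positions, the expected labeling index is

    LI(t) = GF · e · min(1, (Ts + t) / Tc)

with label-detection efficiency e (default 1, appropriate for a saturating
dose): at t→0 the index is the S-phase occupancy GF·e·Ts/Tc, it rises
linearly as cells flow into S, and saturates at t = Tc − Ts when the last
unlabeled cycling cell (the one that had just exited S at t = 0) re-enters S.

Measured curves of this design, however, often show an initial *constant*
phase of length ≈ Ts before the rise — the short-pulse index persists while
the cohort initially in S is replaced one-for-one by entering cells whose
detection lags. The package does not adjudicate between the two readings: it
ships both generators (`agent` and `lagged_rise` modes) and both estimators,
and the lagged-rise generator accepts its initial level independently of
(Ts, Tc) rather than forcing level0 = GF·Ts/Tc, because measured initial
indices are not generally consistent with that identity.

## Estimators

**Breakpoint (default).** The aggregated curve (per-timepoint mean of
per-field indices, each point weighted by its number of fields) is fitted
with a three-segment flat–linear–flat model by exhaustive least squares over
a regular grid of breakpoint pairs (default spacing 0.1 h; ties broken
toward the smallest first, then second breakpoint, making the optimum
deterministic). level0 and plateau are the weighted means of the points in
their flat segments; the middle segment is the straight line joining
(break1, level0) to (break2, plateau). The kinetic reading is Ts = break1,
Tsat = break2, Tc = break1 + break2, GF = plateau; Tc = Ts + Tsat holds by
construction. An optional Nelder–Mead refinement of the breakpoints is
accepted only if it does not increase the RSS. Degenerate inputs raise
specific errors: fewer than 5 timepoints; a curve still rising between its
last two points (by more than `plateau_tolerance`, default 0.03 index
units); a fitted rise amplitude within that tolerance of zero (flat curve).
Breakpoint pairs whose plateau would fall below level0 are inadmissible.

**Linear rise.** The classical inversion fits an OLS line a + b·t through
the pre-plateau points and reads GF = plateau mean, Tc = GF/b, Ts = a/b.
The plateau boundary (number of trailing saturated points, at least 2, with
at least 3 rise points) is chosen by least squares over all admissible
splits rather than by a fixed closeness threshold: this keeps the inversion
exact on noiseless curves even when a rise point happens to lie near the
plateau level. `plateau_tolerance` is used only for the still-rising check.
This estimator assumes an immediately rising curve; applied to lagged-rise
data it is biased upward (the lag inflates the intercept) and is reported
only for contrast there.

## Uncertainty

The bootstrap resamples fields with replacement independently within every
(replicate, timepoint) cell — the field is the unit at which dispersion is
reported — refits each replicate, and takes percentile 95% intervals
(expanded, if needed, to contain the full-data point estimate; the point
estimate itself never depends on the bootstrap seed). Replicates that fail
to fit are dropped and counted; more than 20% failures raises an error
rather than returning a misleadingly narrow interval. Bootstrap refits use
a coarser breakpoint grid (0.25 h) than the point estimate (0.1 h); the
resulting CIs are a quarter-hour lumpy, which is immaterial next to the
sampling noise, and the coarsening keeps a 50-replicate coverage experiment
in the low minutes on one CPU. Condition contrasts (ΔTs, ΔTc) report
bootstrap exceedance probabilities: for a positive observed delta, the
fraction of bootstrap delta draws at or below zero.

## Synthetic-data generator

Defaults mirror the emulated study design: 11 exposure timepoints (1, 4, 8,
10, 12, 14, 16, 20, 24, 38, 60 h), 5 fields of view per sample, 3
biological replicates, field sizes Poisson around 200 nuclei. Per-cell
cycle lengths are lognormal with mean Tc and CV 0.15 (the CV is a modelling
choice — point estimates of Tc in this assay ignore inter-cell variability);
cycle positions are uniform by default, with an opt-in exponential-growth
age distribution f(a) = (2 ln2/L)·2^(−a/L). Condition presets: control
(level0 0.436, Ts 10 h, Tc 31 h), FzM1 (0.434, 16 h, 42 h), FzM1+RARi
(rescue, same as control); the plateau/growth fraction is set to 0.95 for
all arms — it is not a measured quantity here, and only Ts and Tc carry the
scientific contrast. Marker generators use a phase-occupancy model:
P(Ki67+) = GF, P(pH3+) = GF·w/Tc with w defaulting to the G2+M duration
(3 h), P(mitotic figure) = GF·w_M/Tc with w_M = 1 h — at GF 0.95 and
Tc 31 h this puts the mitotic index at ≈3.06%, the scale seen in such
cultures. The Ct generator writes control-condition target genes at a fixed
base Ct, shifts treated means by −log2(fold change), keeps the housekeeping
gene flat, and adds independent Gaussian noise (default SD 0.2 cycles) to
every single well measurement.

What the generator does **not** emulate: spatial field-to-field
heterogeneity beyond Poisson/binomial sampling, replicate-level batch
effects, label toxicity or dose decay over 60 h exposures, cell death and
cell-cycle exit during treatment, segmentation/counting error, or qPCR
amplification-efficiency differences between genes. Passing recovery tests
therefore demonstrates correctness of the inference given the sampling
model, not robustness to those real-data complications.

## Statistics conventions

Marker indices are percentages of positive nuclei per field; the default
SEM denominator pools all fields across replicates (a per-replicate-means
option exists). Group comparisons use the pooled-variance two-tailed
Student's t-test (Welch's by flag); zero-variance degeneracies follow the
conventions t = 0, p = 1 for equal means and p = 0 otherwise. Per-timepoint
curve comparisons apply no multiple-testing correction by default (a
Benjamini–Hochberg option exists but is off), mirroring common practice for
this assay. ΔΔCt testing is done on the additive ΔCt scale with fold
changes reported multiplicatively; the ΔΔCt reference is the control
condition's mean ΔCt, so control replicates scatter around FC = 1 (their
geometric mean is exactly 1 on noiseless data).

## Problem sizes

The recovery experiments use 20 simulated experiments per condition (5
fields × 3 replicates × 11 timepoints, ~200 cells/field each), bootstrap
CIs use 200 resamples, the coverage experiment 50 replicates, and the
type-I-error experiment 100 null curve pairs (1100 tests) — sizes at which
the medians and rates are stable to well within the tolerances checked.

## Known limitations

The breakpoint grid bounds breakpoints to the sampled time range, so truths
outside [first, last − step] timepoints are unrecoverable by design. Tc is
estimated as break1 + break2 exactly as the plateau-persistence reading
prescribes, without GF-correcting the saturation point. The linear-rise
estimator requires at least 3 identifiable pre-plateau and 2 plateau
timepoints on the grid. No percent-labeled-mitoses analysis, flow-cytometry
DNA-content modelling, or mixed-effects nesting of fields within replicates
is attempted.
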