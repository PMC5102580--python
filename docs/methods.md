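# Methods

This note documents the models, estimators and numerical conventions the
package implements, the synthetic world it is validated on, and the design
choices made where more than one reasonable convention exists.

## Task and data model

The simulated experiment shows grayscale object images at a constant 1 Hz
pace in blocks of ten trials, separated by 3 s gray-screen baselines; 32
blocks by default. In *gap blocks*, 60% of trials contain one blank frame
("gap") starting 350, 550 or 750 ms after the stimulus transition and
lasting 100–200 ms (uniform), labeled black/gray and abrupt/gradual; these
labels scale the ground-truth kernel amplitudes through configuration
scalars but are otherwise carried as annotations. In *voluntary blocks*
(12/32 by default) the subject blinks roughly once per second (per-trial
probability 0.9). Spontaneous blinks occur in gap-free trials with
probability 0.2. Blink onset latency and duration are truncated log-normals
(median 450 ms, σ=0.5, truncated to 50–900 ms; median 150 ms, σ=0.35,
truncated to 80–400 ms) — the real distributions are published only as
histograms, so these are free parameters chosen once for plausibility.
Animal trials (the behavioral target) are flagged and excluded from
analysis. A blink and a gap never share a trial, by construction.

Electrode ground truth consists of three kernel families on 4 ms lag grids:
a stimulus response ([0, 1500) ms; transient peak ~25–40% plus a decaying
sustained component), a disappearance dip and a reappearance overshoot
(−250…500 ms; Gaussian bumps peaking ~120–140 ms after the event).
`GroundTruth.from_rois` encodes the published qualitative morphology: early
retinotopic sites (V1–V4, VO) dip (−12% peak; blink dips 1.3× deeper than
gap dips) and overshoot (+15%) for every interruption type; high-level
sites (face-selective FC and non-face-selective N-FC) overshoot for gaps
only and dip weakly. HFB traces are the exact linear superposition of
kernels at event times plus noise — AR(1) with coefficient 0.9 and
stationary SD 5% by default (positively autocorrelated, like real HFB;
1/f-shaped noise is available). Exact linearity is what makes deconvolution
recovery testable to machine precision.

Two higher-fidelity tiers exist for the front-end stages: a raw tier
(500 Hz; 1/f background plus a 70–150 Hz noise carrier whose instantaneous
amplitude follows the noise-free HFB profile) and an ocular tier (pupil
size with smootherstep closing/opening ramps and tracking loss during lid
closure; EOG as slow drift plus a per-blink trapezoid whose half-height
support spans the blink, plus white noise). The quintic smootherstep's peak
second derivative lies at u=(6−2√3)/12 of the ramp — an analytic fact — and
the generator places that point at the scheduled onset/offset, so the
peak-acceleration timing rule recovers the schedule by construction.

## HFB extraction

Eight contiguous 10 Hz bands tile 70–150 Hz. Each band is filtered with a
zero-phase two-pass least-squares FIR; the filter length is set by the
2 Hz transition bandwidth (numtaps ≈ 3.3·rate/transition ≈ 825 at 500 Hz)
because a band this narrow cannot be realized with the short
"3 cycles of the low edge" convention — with ~21 taps, neighboring bands
leak and beat. Filtering is applied in the frequency domain (|H|² on a
reflect-padded signal), which is exactly forward–backward FIR filtering up
to edge handling. Band envelopes (analytic-signal magnitude) are divided by
their temporal means computed over the steady-state core (filter warm-up
margins excluded); the eight normalized envelopes are averaged and
decimated to 250 Hz (FIR anti-alias). Percent signal change is
100·(x/b − 1) with b the mean over inter-block gray baselines — the natural
formula for a unit whose baseline sits at 0%. A degenerate caveat: if a band contains no signal at all (a pure
sinusoid input), its normalized envelope is meaningless ripple; any
broadband floor resolves this, and real recordings always have one.

The artifact scan z-normalizes each channel's first difference (global
mean/SD, excluding previously masked points), takes the across-channel
median of |z|, marks timepoints above 2 and dilates ±200 ms; downstream,
whole trials touching marked points are excluded. On synthetic arrays in
which *every* channel is visually responsive with identical latencies, the
median is no longer robust to the synchronized stimulus transients and the
scan flags them; the pipeline therefore applies the scan at raw fidelity
(where artifacts can exist) and not to HFB-level sessions, which are
artifact-free by construction. With one channel the scan degrades to that
channel with a warning.

## Deconvolution

Each predictor set is a train of non-overlapping 4 ms unit pulses over a
half-open lag window tiled left-to-right; a trailing partial bin is
discarded (this yields 375 columns for [0, 1500) ms and 187 for
−250…500 ms). Stimulus onsets are modeled per category (faces, non-faces),
interruptions per type (gap, spontaneous, voluntary) and — in the full
model — per category; electrode-level maps and permutation refits use the
reduced model without the category split. Onset-locked and offset-locked
interruption predictors live in separate models; a combined model is nearly
collinear because interruption durations are short relative to the windows
(it exists only for stimulus-response plotting). There is no global
intercept: baseline normalization plus the excluded-timepoint handling
define the zero level.

OLS is solved from the Gram system with a Cholesky factorization (the
normal-equations formula is the contract, not the algorithm); exact rank
deficiency is detected and either raised as an error listing the offending
columns or, in pipeline use, resolved by dropping exactly-collinear columns
with a record. Excluded timepoints (animal trials, masked trials, ambiguous
eye-tracking intervals) are removed as rows; this is algebraically
identical to the dummy-nuisance-predictor-per-timepoint formulation (which
`DesignMatrix.with_dummies` materializes) but keeps HC3 well defined — a
dummy column forces leverage 1 and residual 0 at its timepoint, a 0/0 in
the sandwich weight. Leverages are computed row-wise from the sparse design
(each row has only a few nonzeros). HC3 standard errors follow the sandwich
with weights e²/(1−h)²; a leverage of 1 raises a saturated-design error.
Per-lag tests compare beta/se to a standard normal and are FDR-adjusted in
time within each predictor set (Benjamini–Hochberg step-up, via
statsmodels).

Permutation tests and split-half estimation refit the same model many times
with only the grouping of interruption events changed. The
`RelabelRefitter` precomputes, once per session, the fixed-block Gram
inverse, per-event gathers of the response and of fixed-design rows at the
pulse times, and the pairwise pulse-coincidence diagonals; each relabeling
then solves the Frisch–Waugh–Lovell projected system for the interruption
coefficients only. This is exact — a test asserts equality with the direct
full fit to 1e-9 — and reduces a refit to one small dense solve.

A template-subtraction alternative (per-category mean of uninterrupted
trials subtracted before event-locked averaging) is provided both as the
simple cross-check and, with subtraction disabled, as the naive average
whose overlap bias motivates deconvolution.

## Components and split-half estimation

Cluster integrals are Riemann sums (Σ beta·Δt, Δt = 4 ms) over maximal runs
of strictly same-sign timepoints at lags ≥ 0; zeros terminate a run; ties
between equal-magnitude clusters go to the earliest. The dip is the most
negative below-zero integral of the onset-locked trace, the overshoot the
largest above-zero integral of the offset-locked trace. The split-half
estimator randomly halves each event set (stratified by category; odd
counts split ceil/floor with the extra side random per split), fits both
halves as separate predictor sets in one model, determines the cluster
interval on half A and integrates half B over it, averaging 30 splits. Under
the null its expectation is zero, while the plugin estimate is biased in
the cluster's sign — the circularity the procedure removes, verified on 200
noise electrodes.

## Inference

The electrode-level permutation test shuffles gap/blink labels within
face/non-face strata (m = 2000 by default), recomputes the plugin component
difference on the reduced model per permutation, and assigns
p = (b+1)/(m+1); two-tailed p doubles the smaller tail (the correction is
unspecified in words; doubling is the standard choice). A stratum
containing only one event type either raises or, in pipeline use, keeps its
true labels in every permutation (a conditional test). FDR is applied
across all visually responsive electrodes, pooled over patients. The ROI
randomization test draws multivariate-hypergeometric reallocations of the
significant flags over the fixed per-ROI electrode totals (m = 10,000) and
smooths the p-value with the same add-one rule; E_i = 0 cells with O_i = 0
contribute zero to the statistic.

## Screening and blink events

Responsiveness compares per-trial 50–350 ms window means (trials with any
interruption in the window or the preceding 100 ms excluded, animal trials
excluded) with baseline observations, Bonferroni-corrected within patient,
requiring Glass' Δ ≥ 2 from the maximally responding category. Baseline
observations are per-interval means, not raw samples — rank-sum tests on
autocorrelated samples would inflate n; the same interval means define the
Δ denominator SD. Face selectivity is one-sided rank-sum of faces against
every other category, p < 0.05 each, uncorrected; face-selective electrodes
are forced to the FC ROI ahead of anatomy, and anatomical labels are
accepted as metadata (atlas work is out of scope).

Blink detection requires a pupil-loss interval and an EOG artifact within
±100 ms; the artifact score is a robust z of the EOG after removing a 1 s
moving-average baseline (slow drift otherwise swamps the scale). Onset is
the most negative smoothed second derivative (10 ms smoothing; central
differences) in the 120 ms before loss, provided it exceeds 5 robust SDs of
the trace's curvature — otherwise the last valid sample (instantaneous
dropout); offset mirrors this after reacquisition. "Peak acceleration" is
read as the extremum of the signed second derivative in the direction of
the change. EOG-only timing fits, per blink and over ±750 ms, a degree-5
polynomial baseline plus a trapezoid (start, rise, plateau, fall, height)
by bounded nonlinear least squares with the polynomial solved linearly at
each step (variable projection) and three onset multistarts; the threshold
fraction is calibrated by scanning 0–100% of the per-session median
artifact amplitude against pupil-derived durations (ties to the smallest
fraction; 22% when no calibration data exist). Matching is incremental
greedy: each iteration pairs the eligible gap–blink pair (|difference| ≤
50 ms latency / 15 ms duration) minimizing the distance between
paired-subset means, ties broken by the smallest per-pair difference then
the earliest gap; the published procedure is stated iteratively and its
global objective is ambiguous, so the incremental reading is implemented.

## Pipeline, sizes, determinism

`run_pipeline` derives all per-patient, per-stage seeds from one global
seed via seed sequences; identical configurations reproduce every
stochastic output bit for bit (tested). Grand averages weight patients
equally (mean of within-patient means). Interruption types with fewer than
four usable events are skipped — sparser sets produce single-pulse
predictor columns whose standard errors are undefined. The exported
component table matches what a downstream mixed-effects group analysis
would consume (electrode, patient, ROI, interruption, category, component,
integral), with an optional sign-invert/shift/log transform; fitting that
model is out of scope.

Validation experiments run at desk scale: 6–12-block sessions, reduced
windows (stimulus [0, 600)–[0, 1000) ms, interruptions −100…300/400 ms),
200 simulated electrodes for sampling distributions, m = 500 permutations
for the calibration study. These sizes characterize the estimators — exact
recovery, bias removal, type-I error — not patient-scale effect sizes; the
published electrode counts and F statistics are not reproduction targets.
Passing tests on this world show the machinery is correct under linear
superposition, stationary noise and known kernels; they do not speak to
nonstationarity, epileptiform artifacts, imperfect event timing or
electrode heterogeneity in real recordings, beyond what the artifact scan
and exclusion logic are designed to absorb.

## Known limitations

- The synthetic world is exactly linear in events; real HFB saturates and
  adapts. Recovery guarantees are therefore statements about the estimator,
  not about cortex.
- The raw tier's carrier is stochastic narrowband noise, so single-trial
  extracted envelopes are intrinsically noisy; envelope fidelity is
  assessed on smoothed or trial-averaged traces.
- The artifact scan assumes most channels are quiet at any timepoint;
  fully synchronized arrays (every channel responsive, identical latencies)
  violate this and are handled by construction rather than by the scan.
- The combined onset+offset model is exposed but near-collinear, as in the
  original design; no regularized variant is provided.
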