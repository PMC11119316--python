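# Methods

This note documents the models, estimators and numerical choices behind
`gazexplore`, and what the synthetic-data experiments do and do not show.

## Coordinate handling

Eye-tracker exports give gaze in screen pixels. Each axis is converted
independently to degrees of visual angle about the screen center:
`angle = atan((px − center_px) · pitch_cm / viewing_distance_cm)`, the
exact geometry for a flat screen viewed on-axis. A linear small-angle
conversion is available for comparability with analyses that use a flat
deg/px factor; at the default geometry the two differ by < 0.2% within
10° of center. The default `ScreenGeometry` (1280 × 1080 px, 60 cm
viewing distance) needs a physical panel size, which eye-tracker files do
not record; the shipped 47.6 cm × 26.8 cm is an explicit assumption (a
typical 22-inch panel) and should be overridden when the real monitor is
known, since pixel pitch scales every velocity and every grid cell.

Blinks and missing samples are a single `INVALID` label: neither carries
a usable coordinate, and no computation distinguishes them. A trial
enters analysis only if it has ≥ 500 valid samples (configurable);
analysis then uses the half-open window `t ∈ [0, 5 s)`, which at exactly
60 Hz is exactly 300 samples.

## Velocity and state features

Speed is the raw first difference of position over the actual timestamp
difference — no smoothing, because the downstream statistics are means
and dispersions of `log v`, not peak detection. A velocity sample spans
records (i−1, i) and takes the label of record i; pairs straddling an
INVALID record produce no sample, and pair-based statistics (the
transition probabilities) skip across such gaps entirely rather than
bridging them.

The log base is base 10 by default and recorded in outputs. Under base
10 the shipped group parameters put fixations near 10^1.04 ≈ 11 deg/s and
saccades near 10^2.13 ≈ 135 deg/s, consistent with standard
velocity-threshold event separation; a natural-log reading would put
saccades at ~8.6 deg/s, below any plausible fixation/saccade boundary.
Samples with v = 0 (possible with quantised coordinates) have no
logarithm; they are excluded from log-domain moments and counted in the
output rather than floored to an arbitrary value.

Per-state moments use the population (1/N) standard deviation. The
transition probabilities are the maximum-likelihood estimates for a
two-state Markov chain: P_FS = (# F→S pairs) / (# pairs starting in F),
and symmetrically for P_SF.

## The exploration metric Λ

The plane of degree coordinates is tiled by an unbounded square grid
(0.5° cells, anchored at the screen's top-left corner in degree
coordinates). Off-screen samples still count — gaze is not clipped.
A(kτ) counts distinct cells among valid samples with `t < kτ`, and

    Λ = (1/N) Σ_{k=k_start}^{N} A(kτ)/(kτ),   τ = 1/60 s, N = 300.

The k = 0 term of a naive sum is 0/0, so the sum starts at k_start = 1;
the prefactor stays 1/N regardless of k_start, preserving the printed
normalisation. A configurable k_start (e.g. 10, making the first window
≈ 0.167 s) is exposed for sensitivity analyses. Λ is invariant under
translation by whole cells but *not* under sub-cell shifts — grid
anchoring is part of the metric's definition, which is why the anchor is
fixed rather than data-dependent; the test suite asserts both halves of
this. Windows are defined by time, not by valid-sample count, so blinks
freeze A(t) without shifting later windows.

## Classifiers

*Λ threshold.* Exhaustive search over midpoints of consecutive distinct
training values (plus sentinels below and above the data), maximising
training accuracy; ties resolve to the lowest qualifying threshold, and
the direction (whether high Λ predicts ASD) is learned, not hard-coded.
If all training values coincide the classifier degrades to the majority
class and is flagged.

*Logistic model.* p = 1/(1 + e^{−L}) with L = β₀ + Σ βⱼ zⱼ on z-scored
features (training mean and population SD; a constant feature gets scale
1). The fit minimises the unregularised negative log-likelihood
(L-BFGS, gradient tolerance 1e−8, iteration cap 5000). On separable data
the unregularised MLE diverges; the optimizer's capped coefficients are
returned with a `separation_flagged` marker, raised when the mean
per-sample NLL falls below 1e−3 (the NLL approaches 0 only under
quasi-separation) or the iteration cap is hit. An optional ridge penalty
is available for separable designs. ASD is the positive class
throughout, fixing the semantics of sensitivity and precision.

*Cross-validation.* Stratified k-fold (default 5) with a fixed seed;
confusion counts are pooled over held-out predictions before ratios are
computed, so each trial is predicted exactly once and the counts sum to
n. Undefined ratios (0/0) are reported as NaN, never as 0. Folds default
to trial-level assignment; because trials from one child are correlated,
participant-level grouping (`Grouping.BY_PARTICIPANT`) is available and
recommended when participant identifiers are meaningful — trial-level
CV optimistically leaks participant identity across folds.

*Feature importance.* Two rankings: |β| on the normalised scale, and
permutation importance (mean accuracy drop over 50 seeded permutations of
one column).

## Group statistics

Student's t (Welch by default — group variances of gaze features are
visibly unequal; pooled available) and the Mann–Whitney–Wilcoxon test,
both two-sided. MWW uses the exact null distribution when the combined
sample is ≤ 20 without ties, else the normal approximation with tie
correction; rank invariance under strictly increasing transforms is
exercised in tests with exp, cube and affine maps, and the exact branch
is checked against full C(8,4) enumeration. The feature report prints
raw p-values (the convention for descriptive group tables) with a
clearly-labelled supplementary Bonferroni column. With both groups
having zero variance and equal means the t statistic is undefined; the
conventional p = 1 is returned with a flag.

## The synthetic generator

The generator inverts the descriptive two-state picture into a sampler:
a Markov chain over {F, S} with switch probabilities (P_FS, P_SF); a
per-sample speed drawn log-normally from the current state's (μ, σ); a
displacement of `speed/rate` along the current heading. Headings are
re-drawn isotropically at every fixation sample (drift/tremor proxy) and
held for the duration of a saccade episode (ballistic proxy). Optional
blinks overwrite runs of samples (default 0.2 s) with INVALID at a
Poisson rate.

Boundary handling is chosen to protect the estimator contract. A step
that would cross a screen edge bounces by mirroring its heading, which
keeps the gaze over the stimulus *and* preserves the step length — the
quantity a first-difference velocity estimate recovers. A genuinely
oversized step (longer than the distance from the current point to the
farthest screen corner; a few percent of the saccade tail at σ_S ≈ 0.7)
cannot fit on any screen: folding or truncating it would systematically
depress the recovered μ_S and σ_S, so instead it overshoots off-screen at
full length and subsequent steps steer back toward the screen. The
consequences are measurable and accepted: planted log-velocity moments
and switch rates are recovered without bias (cohort means land within
one standard error in the shipped experiments), while a noticeable
minority of samples (~15% at the default parameters) sit outside the
screen rectangle during tail excursions. Real recordings differ here:
trackers typically lose, rather than follow, gaze far off-screen. Λ is
insensitive to this choice in the regimes tested — the ASD > TD ordering
of mean Λ holds at every window length from 1 to 5 s.

Per-trial seeds are CRC-32 hashes of (master seed, group, trial index),
so cohorts are reproducible and order-independent. The shipped
`TD_PARAMS` / `ASD_PARAMS` are the published group-mean features of
typically-developed and ASD children (μ_F 1.04 vs 1.20, σ_F 0.437 vs
0.429, μ_S 2.13 vs 2.16, σ_S 0.708 vs 0.621, P_FS 0.0502 vs 0.0617,
P_SF 0.358 vs 0.325). Absolute Λ levels emerge from spatial dynamics the
two-state description does not constrain, so the simulator is expected to
reproduce the *ordering and separability* of the groups, not the absolute
published Λ means — simulated cohorts land in the same few-tens-of-cells/s
range but a few cells/s lower.

What passing tests show: the estimators invert the generator, the metric
and classifier machinery is correct against independent oracles, and the
published group parameters alone suffice to separate the groups through
Λ. What they do not show: performance on real children, where event
labels come from a vendor algorithm, within-saccade velocity profiles
exist, gaze and stimulus content interact, and trials per participant are
correlated.

## Problem sizes and numerical choices

The shipped experiments use cohorts of 30 × 5 s trials per group for
separation/classification checks and 200 × 60 s trials for parameter
recovery; statistical calibration uses 1000 null replicates at n = 20
per group. These sizes put Monte-Carlo error well below the effects
being measured while keeping the default test run fast. Velocity uses
actual timestamp differences, never the nominal rate; all windows are
half-open in time; text round trips of trajectories are bit-exact
(seconds-based timestamps, correctly-rounded string parsing), because a
one-ulp timestamp error can move a sample across a window edge. Every
analysis artifact embeds the seed and a SHA-256 hash of the full
configuration.
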