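# Methods

This note documents the models, numerical choices and limitations of
`lumovar`, in the spirit of a package methods appendix. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Kinematic chain

Marker trajectories of two 3-marker clusters (thorax/T8, pelvis/S1) are cubic
spline resampled per coordinate onto a uniform 100 Hz grid; capture software
in this protocol records at a fluctuating 102/103 Hz and drops occasional
samples. Dropouts up to 0.1 s are bridged by the spline; longer gaps raise an
error naming the marker and interval, because spline extrapolation over long
dropouts is unreliable and marker gap-filling heuristics are out of scope.

Each cluster defines a deterministic orthonormal frame: axis 1 along
p1→p2, axis 3 along the normalized cross product with p1→p3, axis 2
completing the right-handed triad. A two-vector construction (rather than a
least-squares/Procrustes rigid-body fit) is exact for the 3-marker minimum
and keeps the frame deterministic. The lumbar rotation is the thorax frame
expressed in the pelvis frame, `R = Rp' Rt`, decomposed as intrinsic
x–y′–z″ Euler angles in the order flexion/extension → lateral bending →
axial rotation, reported in degrees. Axis convention (documented, not
standardized by the protocol): at upright start the pelvis frame coincides
with the global frame, x mediolateral (positive rotation = forward flexion),
y anteroposterior, z vertical. Decomposition refuses inputs within 1° of
gimbal lock (|lateral bending| near 90°), a posture the seated reaching task
never approaches.

## Cycle metrics

Cycles are delimited by the peaks of the sagittal (flexion–extension) angle
— the most forward thorax orientation. Peak candidates are local maxima of a
zero-phase low-pass-filtered copy (cutoff 4× the movement frequency, the
dominant period being read off the autocorrelation's first peak) with minimum
separation 0.5× the dominant period and prominence ≥ 25% of the signal IQR;
the separation and prominence rules are heuristics chosen for robustness on
smooth quasi-periodic traces and are configurable. Each candidate is refined
to the vertex of a quadratic fitted to the raw signal over ±3% of a period:
detecting on the raw signal directly lets measurement noise spawn spurious
maxima on the flat (upright) portion of the movement, while a raw `argmax`
refinement inherits sample-level noise jitter near the flat peak; the
quadratic vertex is exact to ±1 sample on noiseless data and keeps
noise-induced boundary jitter near one sample at 1° noise (which is what
keeps the MeanSD recovery unbiased; see below).

To exclude transients, only the final 40 of the 45 protocol repetitions are
analyzed (41 peaks → 40 peak-to-peak cycles). CyclSD is the n−1 SD of the
cycle durations. Each cycle is time-normalized to 101 phase samples by cubic
spline (endpoints are knots, hence preserved), then cycles are aligned by
maximizing the circular cross-correlation of the flexion–extension trace
with the ensemble mean — integer shifts on the phase grid, bounded ±10
samples, one refinement pass against the updated mean; the shift found on
the primary axis is applied to all three axes to preserve intersegmental
coupling. The protocol does not specify the alignment channel or search
range; the primary axis and the ±10% bound are package choices (an unbounded
search can lock onto the wrong cycle feature). MeanSD is the mean over the
101 phase points of the n−1 SD across cycles, per axis. Amplitude is the
mean per-cycle maximum minus mean per-cycle minimum (computed on the
unaligned normalized cycles; circular shifts could split an extremum across
the seam). Velocity is repetitions divided by the time span of the analyzed
cycles; whether the protocol's "total time of the trial" includes the five
discarded transient cycles is unstated, and the analyzed-cycle span is used
because it is the quantity the rest of the pipeline is defined on.

## Local divergence exponent

The three angle channels spanning the analyzed cycles are resampled to
exactly 300 × n_cycles samples (12 000 for 40 cycles), removing the
dependence of the LDE on duration and speed. The state space is 6-D: the
three channels plus one 30-sample (10% of a cycle) delayed copy. For each
state, the 15 nearest neighbors by Euclidean distance are found with a
KD-tree, excluding candidates within a Theiler window of 150 samples (half a
cycle) — standard practice for periodic movement data to suppress trivially
close in-time matches; ties are broken by (distance, index) so the search is
reproducible by exhaustive enumeration. Log distances between the forward
images of each pair are tracked for lags 0…300 (one cycle); pairs whose
images run past the series end are dropped per lag, distances are floored at
1e−12 before the log, and curves are averaged over neighbors per reference
point, then over reference points. The LDE is the unweighted OLS slope over
lags 0…75 inclusive (the first 0.25 cycle, lag 0 included as the simplest
reading of "best fitting line"), multiplied by 300 to express log divergence
per cycle; the per-sample slope is also emitted. Reference points with too
few admissible neighbors are skipped with a log message; an all-skipped
state space is an error. The O(pairs × lags) divergence accumulation is
JIT-compiled with numba when available, with an equivalent vectorized numpy
path otherwise (both are cross-checked in the tests).

## Synthetic data

The trial generator emulates the study task: ~45 approximately periodic,
slightly asymmetric reaching cycles at ~0.38 cycles/s, flexion–extension
amplitude 20°, secondary axes 8°. Each axis is an asymmetric raised cosine
(rise fraction 0.45) of a common phase variable; the secondary axes lag/lead
by 0.06 cycles so the 3-channel trajectory traces a genuine loop rather than
a degenerate line. Three noise sources with known ground truth:

- **temporal jitter** — peak-to-peak durations drawn i.i.d.
  N(2.6 s, jitter SD²). Durations are defined peak-to-peak (peaks at integer
  phase) because the analysis segments cycles at the detected sagittal
  peaks; the drawn SD is then directly comparable with the pipeline's CyclSD.
- **process noise** — multiplicative noise on the instantaneous phase
  velocity, producing genuine trajectory divergence that the LDE detects
  (purely additive measurement noise does not create diverging dynamics).
- **spatial noise** — additive per-axis noise, low-pass filtered at 10 Hz to
  resemble kinematic rather than white measurement noise, renormalized to
  the requested SD exactly.

The marker forward model places the pelvis cluster at a fixed global
orientation and rotates canonical thorax offsets by the composed Euler
rotation, making the generator and the kinematics chain exact mutual
inverses (verified to < 1e−6° on full trials).

The cohort generator works at the metric level: per participant a random
log-scale baseline for each metric (between-subject SD 0.22, matched to the
reported interquartile scales), per-condition residuals, and configured
effects — threat multiplies MeanSD_fe and CyclSD by 1.22 (the reported
within-subject magnitude), shifts LDE by +0.10 (~3%), amplitude ×1.05,
velocity ×0.97; the group × EBS interaction inflates secondary-axis MeanSD
in the LBP ∩ high-EBS cell (×1.25). Within-subject residual SDs (0.25
log-scale for the lognormal metrics, 0.18 for LDE) are back-solved from the
reported effect sizes (partial η² ≈ 0.26 for a 22% MeanSD_fe effect at
N = 60 implies a ~0.25 log-scale condition residual), so simulated F ratios
and η² land at the study's scale. EBS scores are integers 0–10 drawn to
respect the fixed dichotomization (≤3 low, ≥4 high) with 15 participants
per group × EBS cell.

What the generator does **not** emulate: soft-tissue artifact, marker
occlusion patterns, non-stationary fatigue drift, inter-axis coupling beyond
a fixed phase lag, or trial-level/metric-level correspondence for cohorts
(cohort metrics are drawn directly rather than computed from 120 simulated
trials). Passing tests therefore demonstrate correctness of the estimators
under controlled conditions, not robustness to every artifact of real
capture data.

## Statistics

Skewed metrics (MeanSD × 3, CyclSD, amplitudes × 3, velocity) are natural-log
transformed (the base only shifts constants; F and η² are invariant); LDE is
left untransformed. The mixed design is decomposed in the standard way:
within-subject effects are multivariate tests of the per-participant
condition differences on the effect-coded between design (intercept ↔ threat
main effect, and so on), between-subject effects are tests on the condition
means. Every effect in the 2×2×2 design has one hypothesis df, for which the
Wilks' Λ F-transform is exact: F = (1−Λ)/Λ · (νe−p+1)/p with
νe = N − 4 = 56, giving the design dfs (5, 52) and (4, 53). Effect coding
with single-column contrasts yields Type III sums of squares for the
(possibly) unbalanced EBS cells, matching common statistics-package
defaults. The implementation is cross-checked against statsmodels' MANOVA to
1e−6 in Λ, and its null type-I error is verified empirically (within
[0.03, 0.07] at α = 0.05 over 1000 null cohorts). Univariate follow-ups
report partial η² = SS_effect/(SS_effect + SS_error), which for 1-df effects
equals F/(F + 56). The nonparametric suite (Mann–Whitney U between groups on
ordinal scores, Wilcoxon signed-rank on paired EBS with the zero-split tie
rule, t-tests on anthropometrics, Spearman correlation between the two EBS
assessments) delegates to scipy. Significance is 0.05 throughout with no
multiple-testing correction, matching the protocol.

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to keep estimates well resolved:
recovery of injected spatial/temporal variability uses 50 seeds of
full-protocol trials (45 cycles); the LDE–process-noise monotonicity grid
uses 20-cycle trials (16 analyzed) at 5 noise levels × 20 seeds, since the
LDE estimate stabilizes well below the full 40-cycle length and the check
concerns ordering, not absolute scale; null calibration uses 1000 cohorts
and power 100. Numerical tolerances: rotation round-trips are exact to 1e−9°,
the forward-model inversion to 1e−6° (spline resampling dominates), spline
idempotence to 1e−12, and exact-arithmetic identities (η², closed-form SDs)
to 1e−9 or better.

## Design notes

- The package uses plain dataclasses + functions rather than
  fit/transform-style estimator classes: the natural data units
  (variable-length time series per trial; a repeated-measures cohort table)
  do not map onto an n_samples × n_features matrix with fit/predict
  semantics.
- C3D container input is not supported; the pipeline reads documented CSV
  dialects for markers and angles. The `c3d` format selector fails with an
  explicit message.
- End-to-end determinism: identical inputs, configuration and seeds produce
  bit-identical outputs; all randomness flows through
  `numpy.random.default_rng(seed)`.

## Known limitations

- The LDE neighbor-exclusion rule (Theiler window) and the fit-range
  endpoint convention (lag 0 included, inclusive end) are package defaults;
  other implementations differ in these details, which shifts absolute LDE
  values slightly without affecting ordering or condition contrasts.
- The peak detector assumes a quasi-periodic signal with one forward reach
  per cycle; it is not a general event-detection tool.
- Between-subject covariates (PCS, PASS, ODI, …) are carried as data and
  summarized nonparametrically only; no covariate-adjusted models are fit.
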