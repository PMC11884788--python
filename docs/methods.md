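# Methods

## Estimator

The joint response distribution of the two channels at the three query
times (result at t, result at Tr, cause at Tc) is approximated as
multivariate Gaussian, under which transfer entropy reduces to

    TE = ½ ln [ Var(X_t | X_Tr) / Var(X_t | X_Tr, Y_Tc) ]  (nats),

with conditional variances computed as Schur complements of the sample
covariance (unbiased, n−1 denominator; the TE ratio is insensitive to a
common factor, so the denominator choice only affects diagnostics).
This equals the mutual-information difference I(X_t; X_Tr, Y_Tc) −
I(X_t; X_Tr); the test suite verifies the identity against a
log-determinant entropy oracle to 1e−10 on random covariance matrices.
The Gaussian form is an approximation for real, mildly non-Gaussian
response distributions; a nonzero Gaussian TE still certifies nonzero
true TE, but values should be read as a Gaussian-family summary, not the
exact functional.  Natural logs (nats) are used throughout; a
`nats_to_bits` helper converts.

Conventions and numerics:

- The variable order everywhere is `(result_t, result_tr, cause_tc)`;
  `fw` uses the dataset's cause channel as cause, `bw` swaps the roles.
  The query default is Tc = Tr < t.
- The Schur-complement code accepts vector conditioners, so Tc ≠ Tr and
  multi-point histories are expressible even though the standard
  analysis conditions on a single reference time.
- Negative TE within 1e−12 is round-off and clipped to zero; larger
  negatives raise.  Singular conditioning blocks are fatal by default;
  an explicit ridge (`ridge=eps`) may be enabled by the caller — silent
  regularization would bias TE.  Sample covariances of constant columns
  warn rather than fail, and the downstream Schur complement decides.
- A minimum of 50 cells is required per TE estimate by default
  (config-adjustable); covariances need n ≥ 3.

## Significance

The null hypothesis TE = 0 is imposed by destroying every element of
the cross-covariance between the cause channel and the result pair:
each null replicate permutes the cause-channel cell assignment relative
to the result channel, preserving both marginals exactly and requiring
no distributional assumption.  1000 replicates are drawn and the upper
1% percentile point of the null TE values is the significance
threshold; a value above the threshold is called significant.  With an
exchangeable uncoupled population this procedure is exact: the measured
type-I error on uncoupled synthetic data is statistically
indistinguishable from 1% (the finite-resample analysis gives
10–11/1001 ≈ 1.0–1.1%).  A Gaussian-redraw null (resampling from the
fitted Gaussian with zeroed cross-covariance blocks) is available via
`null_method="gaussian"`.

Within one threshold computation the same permutations are reused
across the target times t of a course; each query's marginal null
distribution is unchanged and the cost drops by the course length.

For time-course level statements the package uses a detection
convention: a direction of information flow is *detected* when the TE
time course contains at least 3 consecutive significant time points.
At the 1% per-query level an isolated significant point appears in
roughly a third of 35-point courses, so single points are never treated
as detections; the 3-point rule's measured false-call rate on uncoupled
data is a few percent while retaining full power on the feedback
presets.

## TEsum, conditional TEsum and comparisons

TEsum over a named peak window [t_s, t_e] at fixed Tc sums the
significant TE values (insignificant entries contribute zero).
Uncertainty is bootstrap-only: 100 replicates resampling cells with
replacement, resample size equal to the original n, and — by default —
the significance threshold recomputed on each replicate, since the
threshold depends on the resampled covariance; reusing the full-data
threshold is available (`recompute_threshold=False`) and logged by the
caller.  The mean and the 5–95% percentile interval of the replicates
are reported.

Conditional TEsum to the stimulus dose computes a per-dose TEsum in
each bootstrap replicate and averages across doses with equal weights
(the plain average matches the analysis convention; `by_count`
weighting, which matches the formal conditional-TE definition under the
empirical dose distribution, is available).  The pooled (dose-mixed)
TEsum is the non-conditional counterpart.  For a tandem cascade the
pooled value is expected to be at least the conditional one (dose
uncertainty flows through the cause channel); a conditional value
significantly above the pooled one indicates a bypass route from the
stimulus to the result channel that skips the cause channel.

Differences between two TEsum computations resample each side
independently per replicate and report the mean and 5–95% interval of
the differences; significance (the ** convention) means the interval
excludes zero.  No multiple-testing correction is applied by default.
Each side's bootstrap stream is derived from a content hash of its
datasets rather than its argument position, making diff(a,b) and
diff(b,a) exact mirror images under a matched seed, and diff(a,a)
identically zero.

## Preprocessing

Raw inputs are per-cell mean-intensity tables (TIR and epi signals) on
the minute grid.  The response trace is

    response(t) = tir(t)/epi(t) − mean of tir/epi over the 3 frames
                  immediately before stimulation,

so every cell's pre-stimulation response averages to zero by
construction (machine precision).  Before the ratio: linear
bleed-through subtraction between fluorophore channels (coefficients
are a config parameter, default 0 — synthetic data has none; clipping
at zero is opt-in) and basal-drift removal, with two documented
options — a linear fit anchored on the pre-stimulation frames
(default) or subtraction of a reference trend.  Cells in the lowest
20% of time-0 signal intensity are removed jointly from both channels;
`floor(fraction·n)` cells are removed, ties broken by stable cell
order, so the filter is deterministic.  Response intensities are
inclusive window sums of the response trace (integer-minute closed
endpoints); normalization "to the maximum" divides by the maximum of
condition means, not per cell.  Binning by causal response at Tc uses
contiguous equal-width bins between the (possibly tail-trimmed) range
bounds; bins below the minimum count (default 150) are reported but not
returned, never silently dropped.  Missing values are fatal throughout:
bad cells are removed at preprocessing, not patched downstream.

## Simulator

The generator is a Langevin rate-equation cascade with activities
bounded in [0, 1] by saturating terms:

    dS/dt = k_es·E(t)·(1−S) − d_s·S  [− k_rs·F·S  or  + k_rs·F·(1−S)]
    dR/dt = (k_sr·S + k_er·E(t))·(1−R) − d_r·R
    dM/dt = k_rm·R·(1−M) − d_m·M          (optional hidden state)

with F = R (direct feedback) or M (delayed feedback through the hidden
state).  The stimulus enters as E(t) = dose/(dose + K) switched on at
t = 0, with optional exponential decay (rate λ) emulating receptor
desensitization; the pre- and post-stimulation segments are integrated
separately so the input step falls exactly on a step boundary and the
drift keeps its full integration order on each smooth segment (the RK4
order-4 convergence is verified against the exact linear-cascade
solution).  The deterministic drift advances by classical RK4 over each
dt (default 0.05 min; dt must divide the 1-min sampling interval); the
diffusion term is an additive Gaussian increment of standard deviation
σ·√dt per step — a Langevin/Euler–Maruyama treatment of the noise,
order-correct for the drift; a full stochastic Runge–Kutta scheme is
out of scope.  Noisy excursions are reflected at 0 and at capacity
(translocation densities are non-negative).  Trajectories are sampled
on the 1-minute grid with 3 pre-stimulation frames and are
bit-reproducible from the seed.

Cell-to-cell variability is mean-preserving lognormal: independent
multipliers per rate parameter per cell (CV `cell_cv`, default 0.10)
and a per-cell input-amplitude multiplier (CV `input_cv`, default
0.08).  Because the rate multipliers are drawn independently per
parameter, they do not couple the two channels; only the shared input
does.  The input-amplitude variability is deliberately modest: it is a
within-dose common input, and raising it injects genuine backward TE
into even a pure feed-forward cascade (the receptor state becomes a
hidden shared cause), which would blur the tandem/feedback contrast the
presets are built to exhibit.

Preset topologies (archetypes, not fits to any measured cascade):

- `tandem` — E→S→R only.  Defaults k_es=0.8, k_sr=2.0, d_s=0.25,
  d_r=0.5 /min, σ_s=0.10, σ_r=0.015, K=5 (stimulus units), λ=0.03/min:
  a strongly driven cause channel with a low-noise reporter-like result
  channel, giving clearly detectable forward TE at 300 cells and
  backward TE indistinguishable from zero.
- `feedback` — adds R→S with gain 1.5 (negative by default, matching
  the known ERK→SOS-type feedback; positive available), with a stronger
  drive (k_es=2.0) so the working point stays mid-range against the
  feedback, and noise weighted toward the result channel (σ_s=0.03,
  σ_r=0.10) so the loop has fluctuations to transmit backwards.
- `bypass` — tandem plus a direct E→R edge (gain 1.5): the dose signal
  reaches the result channel without the cause channel, producing the
  conditional-greater-than-pooled TEsum signature.
- `common_input` — E→S and E→R with no S–R edge; with `input_cv=0` the
  channels are exactly independent, the uncoupled reference used for
  type-I calibration.
- `custom` — explicit edge gains over species E, S, R, M.

All preset rate and noise values were fixed once at design time using
the large-sample Monte-Carlo oracle (`ground_truth_te`) so that each
archetype expresses its defining qualitative behavior, and are not
tuned per analysis.  For the dose-mixing contrast the natural peak
window is early (Tc = 2 min, t = 3–6 min): at 2 minutes the result
channel has barely responded, so the cause channel still carries fresh
dose information and the tandem/bypass ordering is at its clearest.
Peak-window placements are configuration values in general — real
analyses read them off the measured TE time courses.

What the generator emulates: paired 1-min trajectories with 3 pre-stim
frames, dose-dependent saturating response amplitudes, unimodal and
roughly symmetric joint response distributions, cell-to-cell
variability, and optional feedback/bypass/common-input structure.  What
it does not emulate: measurement artifacts (bleed-through, drift,
segmentation errors), receptor-level kinetics, multi-peak TE fine
structure of real signaling data, day-to-day batch effects, or any
quantitative fit to measured SOS/RAF responses.  Pipeline tests passing
on this generator therefore validate the statistical machinery and its
qualitative topology inferences, not biological parameter values.

## Problem sizes and defaults

Defaults mirror the standard experimental design: ~300 cells per dose,
doses {0.1, 1, 10, 100} (0 = vehicle), 60-min records sampled at 1 min
with stimulation at minute 0, TE time courses for Tc = Tr from 1 to
35 min, 1000 null resamples with the upper-1% threshold, 100 bootstrap
replicates with the 5–95% interval.  The test suite exercises the same
machinery at these sizes where the property demands it (type-I
calibration at 300 cells over 1000 trials; topology discrimination over
20 independent 300-cell runs; bootstrap-mean stability at 1317 pooled
pairs) and at smaller sizes for unit-level checks.

## Known limitations

- The Gaussian approximation understates tail dependence; strongly
  bimodal joint responses (e.g. all-or-none switching) would need a
  different estimator family, which is out of scope.
- TEsum sums only significant values, so it is slightly biased upward
  at small n (significance selection) — visible when comparing groups
  of very different sizes; comparisons in this package always bootstrap
  both sides at their own n.
- The permutation null assumes cells are exchangeable within a dataset;
  strong batch structure should be handled by splitting datasets per
  batch (the manifest supports replicate labels).
- The bootstrap interval is a percentile interval; no BCa or studentized
  correction is applied (matching the standard 5–95% convention).
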