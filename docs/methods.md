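# Methods

`cmgmotion` analyzes the 1-D motion of fluorescently labeled proteins
(the motivating case is the CMG replicative helicase) on optically
trapped DNA imaged by confocal scanning. This note documents the models
and procedures the package implements, the parameters that matter, and
the choices made where the design was genuinely open.

## Coordinate and unit conventions

Positions along the DNA are 0-based base pairs (bp); the pixel→bp map
is affine with a default slope of 150 bp/px (50 nm pixels at
0.333 nm/bp, so the 72 bp localization error is ≈24 nm). Pixel
coordinates are 0-based and pixel-centered. Folded distances from the
DNA center are reported in kbp. Times are seconds; the single-color
frame interval is 5 s.

## Synthetic data

The generator (`cmgmotion.synthetic`) is a first-class component: it
defines the statistical conditions every downstream stage is validated
under.

* **Trace models.** Static (constant position), freely diffusive
  (Gaussian increments of variance 2·D·Δt; default
  D = 1.5×10⁻³ kb²/s), directed (x₀ + v·t with a random direction sign;
  default v = 5 bp/s), and confined (discretized Ornstein–Uhlenbeck
  about the start position with stationary SD `corral_sd`, default
  100 bp, relaxation time 10 frames — there is no experimental
  generator for confinement, but the α < 0.5 branch needs one).
* **Observation model.** observed = truth + iid N(0, σ_x²) + drift·t,
  with σ_x = 72 bp by default.
* **Lifetimes.** Trace lengths are geometric with mean 25 frames
  (discrete analog of exponential photobleaching survival), floored at
  1 frame; `fixed_length` overrides the draw for calibration fixtures.
* **Boundaries.** Reflecting at the DNA ends by default (absorbing
  optional); downstream QC drops traces near the beads anyway.
* **Rasterization.** Each live fluorophore renders as an integrated 2-D
  Gaussian PSF of SD 2 px (100 nm, consistent with the 250 nm detection
  radius) on a 160×18 px field of 50 nm pixels; per-pixel counts are
  Poisson draws of the expected photons. No further optics (no bead
  images, no vignetting, no dsDNA mechanics) are simulated, so passing
  tests demonstrate correctness of the analysis under the assumed
  noise model, not robustness to instrument artefacts such as focus
  drift, uneven illumination or tether dynamics.
* **Bleaching series.** Piecewise-constant staircases: each fluorophore
  contributes a N(μ_ΔI, σ_ΔI²) level (defaults 300 ± 30 ADU) until an
  exponential bleach time (mean 25 frames), plus Gaussian read noise.
  The true bleach frames can be returned for scoring, because two
  events inside the step-fit resolution are unresolvable in principle.
* **Force traces.** Gaussian noise (σ_F = 0.1 pN) about a 2 pN
  baseline with an optional step artefact.

All randomness flows from explicit seeds (per-stage substreams derived
via CRC32-keyed `SeedSequence` in the pipeline), and identical
(config, seed) pairs are bit-identical.

## Spot detection, localization, tracking

Detection is Laplacian-of-Gaussian blob detection (scikit-image) at the
single scale σ_LoG = r/√2 with r = 5 px, thresholded at 0.5 on the
scale-normalized LoG response — the stated "ADU/px²" unit is
interpreted as applying to that normalized response, and the threshold
is exposed for recalibration. Detections are refined by 1-D Gaussian
fits to the x- and y-projections of an 11-px window (centroid fallback,
flagged, when the fit fails); intensity is the photon sum within the
detection radius. Duplicate detections within 1 px merge, keeping the
brighter. At the default fixture brightness (≥100 expected
photons/fluorophore, 0.1 photons/px background) recall is ≥99% with
≤1 false positive per 100 frames; at 50 photons the noiseless LoG
response is ~0.73, close enough to the 0.5 threshold that shot noise
costs a few percent recall.

Frame-to-frame linking solves the linear assignment problem
(`scipy.optimize.linear_sum_assignment`) on squared distances with
links forbidden beyond 6 px; birth/death alternatives are priced at the
squared cutoff, so every admissible link is preferred to none. A
gap-closing pass joins track ends to later starts across ≤3 missing
frames within the same distance cutoff, greedily by cost with ties
broken by frame index then x. No time penalty enters gap costs (the
choice is documented, not inferred). Colocalization between channels
uses a <2 px (100 nm) separation per frame; a trace counts as
colocalized when at least half of its frames have a partner, and an
empty reference set yields an undefined (None) fraction, distinct
from 0.

## Calibration from static fiducials

dCas9 bound at known sites is static, so its traces measure the
instrument. The pixel→bp map is a least-squares affine fit through
per-site mean pixel positions (trace means are clustered by the largest
gaps; sites must be ≥10 px apart). Drift μ_v and velocity noise σ_v are
the frame-weighted mean and SD of the change-point segment slopes of
fiducial traces — frame-weighting makes them moments of the
distribution of instantaneous velocities. On simulated fiducials with
σ_x = 72 bp and 25-frame traces, σ_v ≈ 0.40 bp/s, and the mobility
cutoff is 5σ_v = 2.0 bp/s. The localization error σ_x is the pooled SD
(denominator Σ(nᵢ−1)) of drift-corrected positions about per-trace
means. Bleaching step statistics come from a best-single-breakpoint
fit of each single-fluorophore series — exact for the one-step model
and free of any circular dependence on the minimum step size it is
about to define — with steps accepted above 4× a
median-absolute-difference noise estimate; ΔI_min = μ_ΔI − 2σ_ΔI then
captures ≥95% (Gaussian: 97.7%) of step sizes. σ_F is fixed at 0.1 pN
with an override rather than estimated.

## Change-point segmentation

Both change-point fits minimize (sum of per-segment L2 costs) +
penalty × (number of breakpoints) *exactly*, by O(n²) dynamic
programming with O(1) per-segment costs from prefix sums; traces are at
most a few hundred frames, so exactness is cheap and the fits agree
with exhaustive enumeration by construction (tested).

* **Photobleaching steps:** piecewise-constant mean, minimum segment
  2 frames, penalty ΔI_min². Steps smaller than ΔI_min are pruned
  smallest-first by merging the two flanking levels into their
  length-weighted mean — which *is* the exact refit of the
  piecewise-constant model on the remaining breakpoints — and
  re-evaluating until all survive. Upward steps (blinking, re-binding)
  are reported but never counted; the fluorophore number is the count
  of retained downward steps. Raising ΔI_min never increases the
  count. Series shorter than 4 frames fall back to a flagged
  range-threshold count.
* **Velocity segments:** per-segment least-squares lines, minimum
  segment 3 frames, penalty 0.3. The penalty is dimensionful (squared
  position); the fit operates on positions in kbp against time in
  seconds, where 0.3 kbp² is a sensible per-breakpoint cost for
  trajectories whose smoothed residuals are a few hundredths of a kbp
  — in bp² the same number would over-segment absurdly. Halving or
  doubling the penalty changes static/mobile calls on a mixed
  200-trace population by <5% (tested). Every detection inherits its
  segment's slope as its instantaneous velocity v_CPA.
* **Force jumps:** the same piecewise-constant machinery on the force
  signal with threshold 2σ_F = 0.2 pN and, by analogy with the
  intensity fit, penalty (2σ_F)²; the minimum segment is 4 frames
  because two-sample noise means fluctuate by ~σ_F and would
  masquerade as jumps. The trace is truncated before the first
  surviving jump.

## Kalman smoothing

Before segmentation each trace is denoised with a linear-Gaussian
state-space smoother: local linear trend (position, velocity) with the
position observed. Process covariance, observation variance and
initial state are fitted per trace by expectation-maximization
(Shumway–Stoffer, ≤10 iterations, relative log-likelihood tolerance
1e-4), followed by Rauch–Tung–Striebel smoothing. On numerical failure
the raw series is returned and flagged. Smoothing is shift-equivariant
and leaves constant series unchanged.

## Trace quality filters

Applied in order, with every input trace accounted for exactly once:
(1) truncate at the first force jump >2σ_F; (2) drop spots with more
than 5 fluorophores (aggregates); (3) drop traces starting or ending
within 1 kbp of a bead; (4) drop traces starting after frame 3;
(5) omit each trace's last frame (bleaching mid-frame distorts it);
(6) retain only traces of ≥14 frames. Rule ordering matters: a
14-frame trace dies at rule 6 because rule 5 leaves it 13 frames.

## Motion statistics

Static vs mobile: a trace is mobile iff any drift-corrected segment
slope exceeds the 5σ_v = 2.0 bp/s cutoff; under the static null
(σ_x = 72 bp, 25 frames) the false-mobile rate is ≤5% and decreases
with the cutoff. Drift correction is x(t) − μ_v·t from the trace's
first frame. The mean velocity of a trace is |net displacement| /
duration (the path-length variant is also computed, since "normalized
by the length of each trace" admits both readings; net displacement is
reported). Processivity is |net displacement| in kbp. Initial position
is the mean of the first three frames; distances fold about the DNA
center. Histogram bins: 700 bp (positions), 2.5 bp/s (instantaneous
speeds), 1.0 bp/s (mean speeds and v_CPA), 0.5 kbp (processivity),
0.25 (α, with 0.5-wide class bins).

**Direction persistence** is the pooled fraction of consecutive
segment pairs with the same slope sign (exact zeros skipped). A caveat
discovered while validating: for simulated Brownian traces at the
default parameters the measured persistence is ~0.3, *not* the 0.5 one
would quote for independent increments. Optimal change-point fits
place breakpoints at path reversals, so consecutive fitted segments
alternate direction more often than chance; the 0.5 null applies to
increment signs, not to fitted segment signs. Persistence values from
segment fits should therefore be compared against a simulated — not
analytic — random-motion baseline.

## Anomalous diffusion

The time-averaged MSD uses all overlapping pairs (non-overlapping
available): MSD(k) = ⟨(x_{i+k} − x_i)²⟩, k = 1..n−1. Its model is
MSD(τ) = D_α τ^α + 2σ_x², and α comes from unweighted least squares on
log(MSD − 2σ_x²) vs log τ over lags 1..τ_M with
τ_M = clamp(round(0.33·n), 5, 50) (round half-even; the fraction's
rounding mode is unspecified upstream). Lags at or below the noise
floor (MSD ≤ 2σ_x²) are excluded; with fewer than two usable lags the
trace is flagged degenerate and treated as confined. α is clipped to
[0, 2] (clipping the unconstrained estimate rather than bounded
optimization — simpler and exact on noiseless input, where the fit
recovers (α, D_α) to ≥6 significant digits). Classes: [0, 0.5)
confined, [0.5, 1.5) freely diffusive, [1.5, 2] unidirectional. The
σ_x entering the correction is the calibration value, not per-trace.

Diffusion coefficients for freely diffusive traces refit
MSD = 2Dτ + 2σ_x² (1-D: slope 2D, not 4D) by weighted least squares
through the origin of the corrected MSD, weights = pairs per lag, over
the first max(2, round(n/10)) lags; an alternative "optimal" mode picks
the lag count from the reduced localization error
x = σ_x²/(D·Δt) via the fixed-point rule p = 2 + 2.3·x^0.52. Neither
short-lag rule is asserted to be the published optimal-points
prescription; both are documented interpretations. Negative fits
report D = 0, flagged.

## Validation studies

The α-error study simulates 512 diffusive and 512 constant-speed
traces (D = 1.5×10⁻³ kb²/s, v = 5 bp/s, σ_x = 72 bp, geometric
lifetimes of mean 25 frames, 5 s frames) and tabulates the SD of
fitted α among traces at least m frames long, m = 5..30 ("minimum
trace length" is read as a retention threshold over the lifetime
population; fixed-length simulation is available for sensitivity).
σ_α is the sample SD of fitted α among retained traces; the bias
(mean − true α) is tabulated alongside. At the 14-frame threshold
σ_α ≈ 0.39–0.44 in both populations — below the 0.5 separability
requirement for the α ≈ 1 and α ≈ 2 classes. In this implementation
the *smallest* qualifying threshold is 10–12 frames (stable to ±2
across seeds), so 14 frames is sufficient though not minimal here.
Rows retaining fewer than 20 traces are flagged, not dropped. The
classification study reports per-population class fractions with
standard errors of proportion √(p(1−p)/n); the exact two-sided
binomial test sums all outcomes no likelier than the observed one
(scipy `binomtest`, cross-checked against enumeration).

The classification-study length distribution (unspecified upstream) is
the same geometric mean-25 lifetime model truncated at ≥14 frames
after filtering. The experimental fractions themselves (e.g. the
mobile fraction with ATP) depend on instrument data and are out of
scope.

## Problem sizes and runtime choices

The studies run at their full stated scale (512 + 512 traces). Module
tests use smaller populations chosen so each Monte-Carlo assertion
sits ≥3 SE from its threshold: 100–500 traces for recovery checks,
10⁴–2×10⁴ draws for distributional invariants, 500 series for the
step-count recovery rate, exhaustive oracles on ≤20-frame series and
≤6-spot frames. The end-to-end rendered fixture uses ten co-moving,
well-separated spots: crossing spots are unresolvable at the linking
stage for any nearest-neighbour tracker and would measure the scene
rather than the pipeline.

## Known limitations

No 3-D detection; no per-frame PSF fitting beyond projection
Gaussians; no chromatic registration beyond the crosstalk ratio; no
labeling-efficiency deconvolution of fluorophore counts; no
splitting-event or backtracking detection; no HMM state switching
within traces; the synthetic origin position on the DNA is a free
parameter. The HDF5 instrument-export reader is not implemented —
scan I/O is multi-page TIFF plus TSV sidecars.
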