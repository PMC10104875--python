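# cmgmotion

Single-molecule motion analysis of fluorescent proteins on optically
trapped DNA — built for confocal-scan experiments on the eukaryotic
replicative helicase CMG, and usable for any assay that tracks
diffraction-limited spots along a tethered DNA axis.

From photon-count scan stacks (or their synthetic twins) the package:

1. **detects** spots with a Laplacian-of-Gaussian detector
   (σ_LoG = r/√2, r = 5 px) and localizes them to subpixel precision by
   Gaussian fits to the intensity projections;
2. **tracks** them across frames by solving the linear assignment
   problem (squared-distance costs, 6 px link cutoff, 3-frame gap
   closing), and tests two-color colocalization (<2 px);
3. **calibrates** against static dCas9 fiducials: pixel→bp map, drift
   μ_v, velocity noise σ_v, localization error σ_x, and bleaching step
   statistics (ΔI_min = μ_ΔI − 2σ_ΔI);
4. **counts fluorophores** per spot from photobleaching staircases via
   an exact penalized change-point fit (L2 cost, penalty ΔI_min²) with
   smallest-first pruning;
5. **filters** traces (force-jump truncation, aggregate removal,
   bead proximity, late starts, last-frame omission, ≥14-frame
   retention);
6. **segments** Kalman-smoothed traces into linear pieces by
   change-point analysis (min segment 3, penalty 0.3), classifying each
   trace static vs mobile against a 5σ_v = 2.0 bp/s cutoff; and
7. **classifies motion** of mobile traces from the time-averaged MSD,
   MSD(τ) = D_α τ^α + 2σ_x², fitting α on
   log(MSD − 2σ_x²) = log D_α + α log τ up to τ_M = 33% of the trace
   length: α ∈ [0, 0.5) confined, [0.5, 1.5) freely diffusive,
   [1.5, 2] unidirectional, with diffusion coefficients from an α = 1
   refit.

A synthetic-data module stands in for the instrument (Gaussian PSF +
Poisson rasterization, Gaussian localization noise, exponential
photobleaching, drift, crosstalk, force-jump artefacts), so the whole
chain is testable offline. See `docs/methods.md` for the models and
the design choices.

## Worked example

`examples/` holds one short script per capability. Calibrating from
simulated static fiducials (`examples/03_calibrate_from_fiducials.py`):

```text
drift mu_v          = +0.377 bp/s  (simulated truth +0.380)
velocity noise      = 0.387 bp/s
mobility cutoff     = 1.94 bp/s  (5 x sigma_v)
localization error  = 70.4 bp    (simulated truth 72)
```

The estimators recover the injected drift and noise; the 5σ_v cutoff is
what separates static from mobile spots downstream. Classifying one
trace of each kind (`examples/04_motion_classification.py`):

```text
static     -> static  mean |v| = 0.24 bp/s, processivity = 0.05 kbp
diffusive  -> mobile  mean |v| = 0.08 bp/s, processivity = 0.02 kbp, alpha = 0.99 (free_diffusive), D = 1.33e-03 kb^2/s
directed   -> mobile  mean |v| = 5.49 bp/s, processivity = 1.07 kbp, alpha = 2.00 (unidirectional)
```

The diffusive trace (generated with D = 1.5×10⁻³ kb²/s) is recovered as
freely diffusive with α ≈ 1 and a diffusion coefficient near truth; the
constant-speed trace (v = 5 bp/s) is unidirectional with α = 2. The
trace-length study (`examples/05_alpha_error_study.py`) prints the
σ_α-vs-retention table showing that a 14-frame minimum keeps the α
error below 0.5 for both the α = 1 and α = 2 populations.

A thin CLI mirrors the library:

```bash
cmgmotion simulate --model diffusive --n-traces 64 --out simulated
cmgmotion validate --seed 1 --out validation
cmgmotion run-all --seed 1 --out pipeline_out
```

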