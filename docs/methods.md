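# Methods

## Model

`ndvigap` treats inter-sensor NDVI correspondence as a one-dimensional
regression problem: at a fixed 16-day composite period, the fine-sensor
NDVI `y` of a pixel is modelled as an unknown monotone, generally nonlinear
function of the co-located coarse-sensor NDVI `x`, plus noise.  A linear
model is deliberately not assumed — band placements, point-spread functions
and compositing differences between sensors bend the relationship.

The regressor is a 1–H–1 feedforward network with tanh hidden units and a
linear output,

    ŷ = b₂ + Σⱼ w₂ⱼ tanh(w₁ⱼ(2x − 1) + b₁ⱼ),   j = 1..H,

so a weight vector has 3H + 1 entries (16 for the default H = 5).  Inputs
in [0, 1] are affinely mapped onto [−1, 1], the natural working range of
tanh; predictions are clamped to [0, 1] at inference only.  Fitness
evaluation and gradient refinement both use the unclamped linear output:
clamping inside training would create zero-gradient plateaus and flat
fitness regions that stall the search without changing the optimum for
targets inside [0, 1].

### Training

Weights are found in two stages.

1. **Genetic algorithm.**  Real-coded population of 10 chromosomes drawn
   uniformly from [−5, 5] per gene; fitness 1/(MSE + ε) with ε = 1e−12
   (strictly positive, as roulette selection requires, and ordering-
   equivalent to MSE); roulette-wheel selection; two-point crossover with
   probability 0.4; per-gene Gaussian mutation with probability 0.2 and
   scale 0.1 × gene range = 1.0; elite count 9; at most 50 generations,
   stopping early when the best fitness improves relatively by less than
   1e−5 over a 10-generation stall window.  Elitism makes the best-fitness
   trace non-decreasing, which is asserted in the tests on every run.  An
   elite count of 9 out of 10 leaves a single non-elite slot per
   generation; the library keeps this configuration as the method's
   canonical setting but emits a warning, because exploration rests almost
   entirely on one offspring per generation.
2. **Gradient refinement** (on by default, recorded in provenance).  From
   the GA solution, L-BFGS with the analytic gradient of the training MSE,
   tight tolerances (ftol 1e−15, gtol 1e−12) and a final safeguard that
   rejects any result worse than the starting point, so the training MSE
   never increases.  A plain backtracking gradient-descent mode (`method=
   "gd"`) is kept as a dependency-light alternative.  The division of
   labour — global search by the GA, local polish by gradients — is the
   classical construction for GA-trained networks.

Training pairs are clear-sky (coarse, fine) NDVI samples at the same pixel
and period on a common grid, 1000 uniform random points per scene pair by
default, split 80/20 into training and validation; RMSE, MAE and Pearson r
are reported on the held-out 20% with clamped predictions.  Both pairing
directions are supported: coarse replicated up to the fine grid (default;
each coarse pixel then appears in up to factor² pairs, a statistical
dependence the uniform sampler does not correct for) and fine aggregated
down to the coarse grid (used by the direction-comparison experiment).

### Reconstruction

Pixels flagged CLOUD, CIRRUS, SHADOW or MISSING (or already nodata) in the
fine scene receive `model(coarse)` where the coarse pixel is valid; clear
pixels are copied bit-exactly; pixels invalid in both sensors stay nodata —
the method has no spatial-interpolation component, so double gaps are
honestly reported rather than invented.  No blending is applied at fill
boundaries; the output records preserved/filled/unfillable counts instead.

## Rasters, calendar, resampling

Grids are row-major, north-up, origin at the outer corner of the top-left
pixel.  Inputs must be co-registered on grids related by an integer
resolution factor; a geometry-mismatch error enforces this, and
reprojection is out of scope.  The year is divided into 23 fixed 16-day
composite windows anchored at January 1, the last window truncated at
December 31; date-to-period mapping is `min((doy − 1) // 16 + 1, 23)`.
Multi-date stacks collapse to one window by per-pixel maximum over valid
values.

Fine→coarse resampling is the block mean over valid pixels, with a
minimum-valid-fraction of 0.5 below which the coarse pixel is nodata (a
nearly empty block should not masquerade as an observation).  Coarse→fine
is nearest-neighbour replication by default — value-preserving, no
fabricated intermediate NDVI values — with bilinear offered as an option.
Dimensions not divisible by the factor are cropped with a warning.
NDVI < 0 (water, snow, cloud residue, bare rock) is filtered to nodata at
preprocessing, before pairing.

## Metrics

RMSE, MAE, Pearson r and PSNR (10·log10(max_pred²/MSE), dB) operate on the
jointly valid pixel set of the selected support (all valid pixels, filled
pixels only, or clear pixels only); the support rule is recorded in every
report.  MAE ≤ RMSE (Jensen) is asserted on every evaluation.  PSNR of
identical inputs is reported as infinity, a distinguished value rather than
an error.

Two readings of "R" are reported separately: Pearson correlation over
pixels, and a scene-series efficiency coefficient
R = 1 − Σ(Xᵢ−Yᵢ)²/Σ(Yᵢ−Ȳ)² over per-scene means, which is 1 only for exact
agreement and can be negative — the two are not interchangeable, so the
package never conflates them.

SSIM uses global image statistics (no sliding window, since window
semantics would be an arbitrary addition for single-support scoring), with
c1 = (0.01·L)², c2 = (0.03·L)², L = 1.0 for NDVI in [0, 1] by default.  The
standard form, with c1 in both the numerator and denominator of the
luminance term, is the default because it alone satisfies SSIM(x, x) = 1; a
variant that omits the numerator c1, which appears in some method
descriptions, is available behind `as_printed=True`.  An 8×8 sliding-window
mean-pooled mode exists as an option.

## Synthetic study conditions

The scene generator is the package's test bed and defines its default
study conditions: a 256×256 fine grid at 30 m, coarse/fine factor 8 (the
true 250/30 ratio is non-integer; 8 keeps block correspondence exact and is
the documented deviation from real sensor geometry), 23 periods per year,
noise σ = 0.02 on both sensors, 30% cloud cover.

The truth field is a smoothed random partition into four land-cover
classes (winter baselines 0.10–0.22 NDVI, seasonal amplitude shares
0.25–1.00 of the 0.4 default amplitude), modulated by a unimodal seasonal
weight sin(π(p − ½)/23) — NDVI rises to a mid-year peak and falls, the
cropland/forest trajectory — plus low-amplitude smoothed texture, clipped
to [0, 1].  Class boundaries are Gaussian-smoothed so sub-block
heterogeneity stays near 0.02 NDVI: realistic for vegetated scenes at this
scale, and essential to note because filled-pixel error can never beat the
sum of sensor noise and sub-block heterogeneity, the irreducible floor the
recovery tests are calibrated against (not zero).

The coarse scene is g(block mean of truth) + noise with the monotone
distortion g(v) = v^0.85 by default (logistic and identity alternatives
included); g is invertible on [0, 1], so the learning task is well-posed.
The observed fine scene is truth + noise, clipped to [0, 1], with
cloud/shadow pixels set to nodata.  Cloud masks are unions of random
elliptical blobs (scale 12 px) grown until the masked fraction reaches the
target, with a shadow rim displaced by a fixed offset.  All randomness
derives child streams from crc32(master seed, period, component name), so
every artifact is a pure function of (config, period) and adding a
component never shifts existing streams.

What passing on these scenes does **not** show: robustness to
mis-registration, non-integer resolution ratios, BRDF and view-angle
effects, sensor-specific band differences, snow/water confusion, or real
cloud-mask errors.  The synthetic results demonstrate the machinery —
correct pairing, a trainable and refinable network, exact preservation of
clear pixels, honest error accounting — not radiometric realism.

## Numerical choices and degenerate inputs

- Nodata is a boolean mask in memory; on disk a sentinel (−9999) recorded
  in file metadata.  Nodata never enters arithmetic.
- Metrics raise on empty supports, constant inputs where correlation or the
  efficiency denominator is undefined, and zero peak with nonzero MSE.
- The 80/20 split uses `round(0.8 n)` clamped so both sides are non-empty;
  splits, samples and GA runs are deterministic per seed (bit-identical
  outputs, asserted in tests down to file bytes for the CLI).
- Crossover cut points are uniform on [0, L]; mutation may leave the
  initialization range [−5, 5] (bounds apply to initialization only).
- Scene-pair experiments cap the sampled point count at the pairs available
  in the smaller arm so compared arms always train on equal sample sizes.

## Problem sizes

Default test and reproduction runs use one 256×256 scene (1024 coarse
pixels), 1000 training points, five training replicates for
self-validation and ten for the direction comparison — sizes chosen so a
full reproduction completes in seconds on one core while keeping every
statistical check (binomial bounds at 40,000 selection draws, 10,000
mutation draws, 200 sampling replicates) well-powered.

## Known limitations

- One pooled model per training set; per-period models are supported but
  the default follows the pooled protocol.
- Single scalar input; no neighbourhood windows or multi-band predictors.
- No temporal smoothing across periods and no disturbance detection; the
  method fills gaps, it does not reinterpret anomalies.
- The GA configuration with elite count 9/10 is kept for fidelity to the
  method's canonical parameterization; with the gradient-refinement stage
  the final accuracy is insensitive to it, but pure-GA mode
  (`refine_flag=False`) converges noticeably slower and noisier.
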