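# Methods

This note documents the models, parameter choices and numerical
decisions behind ccflow, and what the synthetic experiments do and do
not establish about real data.

## Raster model

All en face images are 2-D float grids in [0, 1] with an isotropic
physical pixel pitch (µm/px) and a modality tag (`octa_cc`,
`octa_scp`, `oct_choroid`). The default raster is 300 × 300 px for a
3 × 3 mm field (10 µm/px), matching the A-scan spacing of swept-source
devices in this scan pattern; the instrument's true raster is not
publicly documented, so the pitch is configurable and recorded in
every output sidecar. Binary masks carry an explicit
`foreground_meaning` (`bright_signal`, `flow_void`, `pachyvessel`) so
that inversion semantics are always stated, never implied.

## Synthetic scene model

The generator provides the ground truth the study's undeposited images
cannot.

* **Meshwork and voids.** Lobule centers are laid on a jittered grid
  (default lobule diameter 400 µm, the scale of choriocapillaris
  lobules in the posterior pole). Flow voids are ellipses with
  gamma-distributed areas (shape 4, mean = requested mean void size,
  default 790 µm²) stamped at centers sampled preferentially near the
  inter-lobule boundaries, with a blue-noise exclusion radius sized to
  the expected void density so distinct voids stay distinct. Stamping
  stops when the target area fraction (default 0.13) is reached, so
  the realized fraction is exact to within one void. The void mask and
  its complement (perfused capillaries) partition the field by
  construction.
* **Pachyvessels.** 150–400 µm wide smoothed random-walk ribbons enter
  from the field border until the requested area fraction (≤ 0.5) is
  reached; on small fields an eroding backstop enforces the cap.
* **Contrast.** Rendered choriocapillaris reflectance is deliberately
  low contrast: perfused 0.85, void floor 0.40. Flow voids on real
  averaged choriocapillaris slabs retain a substantial signal floor
  (noise floor and through-slab projection), which is precisely the
  low-contrast regime the Phansalkar rule is designed for. This choice
  also makes the threshold cross near the midpoint of band-limited
  edge ramps, so the measured void area is an approximately unbiased
  estimate of the crisp truth mask (see *Resampling*, below). The
  structural choroid scan is the opposite regime: stroma 0.85, vessel
  lumens 0.03, plus additive Gaussian noise (default sd 0.05).
* **Acquisition.** Each of the default nine frames receives a rigid
  motion (translation sd 2 px, rotation sd 0.5° about the field
  center — fixation jitter surviving device tracking) and unit-mean
  gamma multiplicative speckle, then clips to [0, 1] (sensor
  saturation). The default shape 10 gives a single-frame SNR ≈ 3: one
  frame looks granular, nine averaged frames resolve the meshwork,
  reproducing the qualitative behavior that motivates averaging.
  Because of clipping, the variance law var = base²/shape is exact
  only away from saturation; the clipped mean and variance have closed
  forms used by the tests. The SCP reference frame of each pair is a
  high-contrast curvilinear network sharing *exactly* the motion of
  its choriocapillaris frame — the property the registration stage
  relies on.
* **Cohort tables.** Per-eye metrics are drawn from the two groups'
  published mean ± sd (PPE: age 62.5 ± 8.6 y, SFCT 374.5 ± 81.5 µm,
  1483 ± 154 voids, 1.16 ± 0.18 mm², 790 ± 144 µm²; controls: 65.2 ±
  9.9, 248.7 ± 35.3, 1826 ± 319, 0.91 ± 0.16, 520 ± 138), truncated to
  positive support; sex by per-group Bernoulli (25/32 and 18/30 male).
  The three flow-void metrics are drawn independently — these rows
  stand in for a per-eye summary table, so the count × size = area
  identity is not enforced on them (it is enforced on every *measured*
  metric). The RPE-to-choroidal-vein distance is drawn conditional on
  pachyvessel presence (64.0 ± 19.6 µm with, 107.2 ± 25.9 µm without)
  and is undefined (NaN) for controls, where it was not measured.

Every generator is a pure function of its seed.

## Registration and averaging

Per-frame rigid motion is estimated on the SCP frames: translation by
phase cross-correlation with sub-pixel refinement (upsampling factor
20) after a σ = 1 px Gaussian presmooth that damps the flat
high-frequency spectrum of speckle; rotation by a grid search (default
±2° in 0.25° steps) maximizing post-alignment normalized correlation,
with parabolic refinement around the best angle. The frame quality
score is that correlation; frames below `min_quality` (default 0.5)
are dropped from the average, the analog of discarding
low-signal-strength or poor-fixation acquisitions. The reference frame
is the first of the stack by default.

**Resampling.** The default resampler is band-limited: translation by
an FFT phase ramp and rotation by the three-shear decomposition, both
exactly invertible and free of interpolation blur. This is not a
cosmetic choice: the flow voids are only ~3 px across, and with
bilinear (or even cubic) spline warping the repeated warp-and-average
chain widens every dark structure by a sizeable fraction of its
radius, biasing the measured void area upward by roughly +20 %.
Spline resampling (orders 1 and 3) remains available via the
`interpolation` argument for comparison. Under either resampler,
pixels whose source location leaves the acquired field are flagged
invalid (NaN) and excluded from the pixelwise mean — never
zero-filled, which would wrap a dark rim around the field and bias the
local threshold.

## Binarization

The Phansalkar threshold is computed per pixel over a circular window
(radius 15 px by default; square available) with mirror padding, using
windowed mean and standard deviation obtained by correlation with the
unnormalized footprint and exact division by the pixel count, so a
constant image reproduces the closed-form threshold to machine
precision. The constants p=2, q=10, k=0.25, r=0.5 are the standard
auto-local-threshold defaults for [0, 1] intensities. Ties break to
background (strict `value > T`), so an all-zero image is all
background. The identical operation serves both rasters: the averaged
choriocapillaris angiogram (inverted → flow voids) and the choroidal
en face scan (inverted → pachyvessel lumens).

## Quantification

Flow voids are connected components of the void mask, 8-connected by
default (4-connectivity by flag), labeled with scipy. No minimum-size
filter and no border exclusion are applied by default (both available
as options); voids touching the field edge count with their visible
area. Metrics: count, total area in mm², mean size in µm², with
count × mean size ≡ total area enforced. Overlap statistics:
pachyvessel portion = vessel area / field area; void-over-vessel = 
void ∩ vessel / void, both in percent, with the latter an explicit
error when the void area is zero. The composite image renders voids
red, vessels green, overlap yellow.

## Statistics

Two-sample t-tests accept raw samples or (n, mean, sd) summaries and
agree exactly between the two forms; Student (pooled) is the default,
Welch by flag. The chi-square test on 2 × 2 tables uses no continuity
correction by default (Yates by flag) — the uncorrected form is what
reproduces the published sex-ratio p-value. Pearson p-values use the
t transform with n − 2 df. Partial correlation regresses both
variables on [1, covariates] and correlates the residuals with
df = n − 2 − k; with no covariates it reduces exactly to Pearson.
"Age/sex-adjusted p" for a group contrast is the partial-correlation
p between the 0/1 group indicator and the metric controlling age and
sex (0/1) — the natural operationalization when only a covariate-
adjusted p is reported. All tests are two-sided; no multiple-testing
correction is applied, matching the study design. The age row of a
report is never age-adjusted (the residual would be identically zero).

## Study driver and problem sizes

`run_all` simulates the full cohort (default 32 + 30 eyes at 300 × 300
px), draws each eye's generative parameters from the group
distributions (void fraction = drawn total area / 9 mm², so
scaled-down fields keep the same fraction), renders, analyzes and
reports. The default frame count for the driver is 5 — enough
averaging for stable measurements at study scale while keeping a full
run in the minutes range; the per-eye API and the acceptance script
use the study's 9 frames. The tests run scaled-down cohorts (2 + 2
eyes, 0.96 mm fields) where only plumbing and determinism are at
stake, and full 300 px fields with 9 frames where recovery accuracy is
asserted. All randomness in a run descends from the single config
seed, and the artifact manifest hashes every output, so equal seeds
give byte-identical runs.

## Known limitations

* The synthetic scene is a two-level reflectance model with geometric
  voids; real choriocapillaris has continuous flow-signal texture,
  projection artifacts and depth-segmentation errors the generator
  does not emulate. Passing recovery tests therefore demonstrates the
  correctness and stability of the measurement chain, not the clinical
  accuracy of absolute void metrics on device images.
* Measured void *count* and *mean size* depend on how touching voids
  merge; the generator's packing makes them land near the published
  scale, but only the total area is controlled exactly by truth.
* Eye motion is modeled as rigid; no torsion-free assumption is made
  but non-rigid distortion (B-scan shear, blink artifacts) is out of
  scope, as are OCT volume synthesis and slab segmentation.
* The Phansalkar threshold's behavior at extreme contrast (near-black
  dark levels) systematically dilates dark structures under any
  resampling; quantitative comparisons between instruments or
  processing pipelines should hold the contrast regime fixed.
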