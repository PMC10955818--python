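# Methods

`octasv` implements intensity-based speckle-variance OCT angiography
(OCTA) construction from repeated or adjacent B-scans, a learned
encoder–decoder that constructs OCTA from single-scan OCT input, and a
speckle phantom that provides the statistical ground truth the method
needs.  This note records the models, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## Speckle-variance OCTA

An OCT volume is a rank-4 grid `[S, R, Z, X]`: slow position, repeat,
depth, fast position.  Flow contrast at a voxel is the per-pixel variance
of intensity over a set of C B-scans,

    SV(z, x) = (1/C) * sum_i (I_i(z, x) - mean_i I(z, x))^2 ,

population-normalized by default (the sample estimator, divide by C−1, is
available via `variance_kind="sample"`).  Two modes share this estimator:

* **temporal** — variance over the first `n` of the R repeats at one slow
  position (conventional multi-scan OCTA; temporal vascular connectivity);
* **spatial** — variance over `n` *adjacent* slow positions in a
  single-scan volume (spatial vascular connectivity), exploiting the fact
  that a vessel's decorrelating speckle continues across neighboring
  B-scans while static tissue stays correlated.

Spatial windows are centered where possible and forward-biased for even
`n`: 2N = (s, s+1), 3N = (s−1, s, s+1), 4N = (s−1, s, s+1, s+2).  At
volume boundaries the `reflect` edge policy (default) mirrors indices so
the output keeps S positions; `clamp` and `valid` are available.  In
spatial mode the volume's repeats are collapsed to one frame per position
— by averaging (default) or by taking repeat 0 (`single_repeat`), which is
the faithful emulation of a genuine single-scan acquisition and is what
the bundled experiments use.

## Registration

Both passes use single-step upsampled-DFT phase cross-correlation
(via `skimage.registration.phase_cross_correlation`), default upsample
factor 100 (precision contract 0.5/upsample for a pure shift).
Intra-frame registration aligns each repeat to the first repeat of its
slow position; inter-frame registration then aligns each position's
repeat-mean frame to its (already corrected) predecessor, so the measured
displacement is directly the cumulative correction.  The previous-frame
reference (rather than a global template) tolerates slow drift and is a
config option.

Corrections are applied as Fourier phase ramps with periodic boundary.
Spline interpolators were rejected because their high-frequency phase
error biases chained registration of broadband speckle (measured ≈8 %
systematic underestimation of a 0.2 px/frame drift with cubic
interpolation; the Fourier ramp is exact).  The sinc ringing a phase ramp
produces around speckle nulls is clipped to keep intensities non-negative
and each frame is rescaled to its original sum, so registration changes
mean intensity by well under 1 %.

## En-face projection and normalization

A slab between two layer surfaces `top(s,x) ≤ bottom(s,x)` is reduced
over the inclusive integer span `[ceil(top), floor(bottom)]` (no depth
interpolation; deterministic).  Default reducer is `max` for angiograms
(preserves thin capillaries) and `mean` for structural OCT.  Empty spans
produce 0 and set a flag.  Normalization linearly maps the
`[p, 100−p]` percentile range to `[0, bit_max]` with p = 0.1 % per tail
(robust to hot pixels); constant images map to zero and are flagged.

## Image metrics and statistics

PSNR is `10·log10(max² / MSE)` with an infinity sentinel for identical
images (excluded from group statistics).  SSIM uses the standard
11×11 Gaussian window (σ = 1.5), K1 = 0.01, K2 = 0.03, computed over
*valid* windows; this is numerically identical to reference
implementations that filter with boundary padding and crop the filter
radius (verified against scikit-image to ~1e−16).  MS-SSIM uses the
standard 5-scale weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333) with
2×2 average-pool downsampling, luminance applied at the coarsest scale
only; when the image is too small for five scales (min dimension must
stay ≥ 11 per scale) the scale count is reduced and the leading weights
renormalized.  Negative mean contrast-structure terms are clipped to 0
before exponentiation.

Group comparisons use classical one-way ANOVA and pairwise two-sided
Student's t-tests (equal variance), reported unadjusted with an
additional clearly-labeled Bonferroni column.

## Vessel quantification

On a binarized en face (default: global Otsu; fixed and adaptive-mean
thresholds available, method recorded in provenance):

* VAD — vessel pixels / total pixels;
* VSD — pixels of the topology-preserving unit-width skeleton / total;
* VPI — vessel pixels 4-adjacent to background / total, with the image
  treated as padded by background (a full mask retains a border
  perimeter).

Conventions: 4-connectivity for the perimeter, 8-connectivity for
skeleton topology.

## The phantom

The phantom supplies what the public record lacks: volumes in which the
flow ground truth is known exactly.  A scene is a stack of retinal-like
reflectance layers (bright inner retina housing the superficial plexus,
hypo-reflective inner nuclear layer, a mid band for the deep plexus,
hypo-reflective outer nuclear layer, bright RPE) with 3-D vessel tubes;
tube interiors are the flow mask, and layer boundaries are exported as
ground-truth surfaces.

Speckle is fully developed: intensity = reflectance · |g|², with g a
unit-variance complex circular-Gaussian field, plus a half-normal noise
floor.  The correlation structure of g decomposes into

* a **distance** part: an anatomy field evolving along the slow axis as
  AR(1) with coefficient `rho_adjacent / rho_repeat` — beam-displacement
  decorrelation accumulates with lateral distance;
* a **time** part: an independent innovation per acquired frame, mixed in
  with weight `1 − rho_repeat` — noise and bulk micro-motion, identical
  between any two frames because the inter-frame period is the same for
  repeats and for neighboring positions.

Consequently every repeat pair has correlation `rho_repeat` (compound
symmetry, which is also what makes temporal flow contrast-to-noise
*increase* with the repeat count — a cumulative AR chain along the repeat
axis would instead accumulate static variance faster than flow variance
and invert the trend), and frames k positions apart have correlation
`rho_repeat · (rho_adjacent/rho_repeat)^k`.  Flow voxels take the low
`rho_flow_*` values on both axes.  Defaults (static repeat 0.98, flow
repeat 0.2, static adjacent 0.9, flow adjacent 0.2, noise floor 0.05) are
chosen so the spatial-connectivity contrast is visible at phantom scale;
they are package choices, not measured values.  For circular-Gaussian
speckle the induced intensity correlation is the square of the field
correlation (verified by Monte Carlo in the tests).

Two named condition sets exist:

* `default_phantom_spec` — anesthetized-style acquisition: high static
  correlations, small per-frame motion (σ = 0.3 px), randomized oblique
  vessels.  Vessel obliquity is 0.2–0.5 px of lateral drift per slow
  step, i.e. a fraction of a vessel radius per B-scan spacing, as in a
  densely sampled volume.
* `human_phantom_spec` — awake-subject acquisition: bulk micro-motion
  lowers the *time* part of the static correlation (repeat 0.88, adjacent
  0.85), making the temporal ground truth itself noisy.  This is the
  regime in which the 3-neighbor spatial window becomes the optimum: the
  2-frame window loses to estimator grain, the 4-frame window to its span
  (vessel smear and the half-frame offset of the forward-biased window).

Motion is synthesized as exact Fourier phase ramps with the ground-truth
shifts recorded per frame, so registration recovery is scored against
exact truth.  An optional blink attenuates a declared band of slow
positions.

What the phantom does *not* emulate: a lateral/axial PSF (voxels are
independent speckle cells), attenuation and shadowing below vessels,
pulsatile flow, projection artifacts, curved layer surfaces, and the
texture-dense capillary meshes of a real retina.  Passing orderings on
the phantom therefore demonstrate that the estimators and the pipeline
respond correctly to the statistical mechanism (flow decorrelation vs
static correlation), not that effect sizes match real retinas.

## The learned constructor

The model maps a C-channel stack of adjacent OCT B-scans (C = 1 or 3,
channels (s−1, s, s+1)) to one OCTA B-scan.  It is a plain convolutional
U-Net — per level two 3×3 conv + ReLU, 2×2 average pooling, nearest
upsampling with skip concatenation, 1×1 head with sigmoid — implemented
directly in NumPy (im2col convolutions, hand-derived gradients, Adam),
which keeps training bitwise deterministic for a given seed.  Defaults:
depth 3, base width 16 (~118 k parameters).  Both losses of the study
design are provided: MSE and a differentiable SSIM loss (L = 1) that
shares the exact valid-window formulation of the metrics module (the two
agree to 1e−6, enforced by test).

Training targets are temporal-4N speckle-variance B-scans,
amplitude-compressed (square root) before scaling to [0, 1] by a global
99.9th-percentile factor: speckle variance is heavy-tailed, and without
compression the squashed network collapses onto the empty background.
The output bias is initialized at the logit of the target mean for the
same reason.  Inputs are scaled by a global percentile of the training
OCT intensities.  Both scales are shared across the 1N/3N arms (fairness)
and stored on the model; prediction squares back into variance units.

The four-arm ablation (1N/3N × MSE/SSIM) trains on ~200 B-scan pairs from
six phantom volumes, validates on one and tests on six held-out volumes,
10 epochs, batch 8, shared Adam learning rate 2e−3 — the rate at which
both loss functions approach their training plateau within that epoch
budget (at 1e−3 the SSIM arm is still far from convergence).  Problem
sizes (32×4×64×64 voxels per volume) are chosen so the full four-model
ablation trains in minutes on one CPU.

Observed behavior: the 3-neighbor input improves held-out MS-SSIM against
the temporal-4N ground truth by a wide margin over single-frame input
(the single-frame model cannot detect flow in the superficial plexus,
where vessel reflectance matches the surrounding tissue — only the
inter-frame decorrelation carries the signal).  The SSIM-trained arms do
*not* beat the MSE-trained arms on this phantom: the SSIM objective has
weak gradients in flat regions whose ground-truth texture is
unpredictable speckle grain, and converges to parity at best.  Its
documented advantage arises on real, texture-dense retinal OCTA; this is
a stated limitation of the phantom, not of the loss implementation.

## Experiment harness

`run_sv_ablation` scores temporal 2N/3N and spatial 2N/3N/4N against the
temporal-4N ground truth of the same registered volume (MS-SSIM and PSNR
on normalized SVP/DVP en faces), then emits long-format CSV, ANOVA and
pairwise-t tables, and a manifest with every seed and configuration;
reruns are byte-identical.  Six phantom seeds per arm mirror a six-volume
test set.  Ground-truth self-comparison rows (MS-SSIM 1, PSNR ∞) are
reported but excluded from statistics.  The spatial-window optimum is
additionally evaluated at B-scan level (percentile-normalized volume
PSNR) under the awake-subject conditions, where the trade-off the window
size controls — estimator grain versus window span — is not masked by
en-face projection and normalization; en-face vessel widening
(vessel area per unit true centerline length) tracks the
pseudo-vessel-doubling artifact of the 4-frame window.

Flow/static contrast is reported two ways: the plain mean ratio (which is
approximately invariant in the scan count, both means scaling with the
same 1−1/N-type factor) and the contrast-to-noise ratio
`(mean_flow − mean_static) / std_static`, which grows with the scan count
as the variance estimator's own noise shrinks.

## Numerical choices and degenerate inputs

* Constant images: registration raises a degenerate-input error (phase
  undefined); normalization returns a flagged all-zero image; Otsu
  binarization returns a flagged empty mask.
* PSNR of identical images returns `inf`; downstream statistics exclude
  non-finite values.
* Model training uses float32; losses and metrics float64.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in the spec/config objects; identical seeds reproduce volumes, training
  curves and CSV outputs bitwise.

## Known limitations

* Rigid translation only; no rotation or non-rigid motion.
* The phantom's static structure is s-invariant apart from vessels, so
  en-face comparisons slightly favor narrow spatial windows (see above);
  real-data effect sizes are not reproduced, only directions.
* MS-SSIM's blur-vs-noise preference is regime-dependent (fine-textured
  images at mild blur prefer blur; strongly blurred smooth images do
  not); the tests pin the regime they assert.
* The learned model is desk-scale; it preserves the I/O contract and the
  skip-connection topology of much larger encoder–decoder designs but
  none of their capacity.
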