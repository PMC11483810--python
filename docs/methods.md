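# Methods

`mesoreg` benchmarks five co-registration strategies for sparse 3D vascular
volumes of the kind produced by raster-scan photoacoustic mesoscopy (RSOM):
two intensity-based affine methods (gradient ascent on mutual information or
normalised cross-correlation), two shape-based affine methods (point-to-plane
ICP on segmentation surfaces, and NCC on Euclidean distance maps), and a
weakly supervised deformable network. Everything runs on synthetic vascular
phantoms with known ground truth, so every stage is testable end to end
without external data.

## Conventions

* Voxel indices are 0-based; physical coordinates (µm) follow the
  voxel-centre convention `x = origin + index * spacing`. The native RSOM
  grid is anisotropic (20 × 20 × 4 µm), and all transforms act on physical
  coordinates so anisotropy is handled exactly once.
* Affine transforms map **fixed-space points into moving-space points**;
  warping pulls moving intensities back onto the fixed grid through the
  transform (linear interpolation for intensities, nearest neighbour for
  masks, zero fill outside).
* Dense displacement fields (DDFs) are stored in voxel units of the fixed
  grid; `warp_with_ddf` samples the moving image at `index + u(index)`.

## Synthetic phantoms

The generator emulates the properties of RSOM scan pairs that make
registration hard, not the physics of photoacoustic image formation:

* **Vessel networks** are random binary branching trees (depth 5,
  branch probability 0.65, radii 8–30 µm with per-generation tapering,
  tortuosity jitter). There is no haemodynamic realism; tubular sparsity
  and branch-point landmarks are what registration sees. The root always
  branches so ≥ 1 branch point exists at depth ≥ 2.
* **Rasterisation** marks a voxel as vessel if its centre lies within the
  segment radius (exact point-to-segment distance); intensity has a linear
  one-voxel soft edge. Masks play the role of the upstream segmenter's
  output (learned segmentation is out of scope; a threshold segmenter is
  provided as a signal-ROI stand-in).
* **Imaging model**: `background + gain · clean · exp(-decay · z_mm)` plus
  i.i.d. Gaussian noise. Defaults: background 0.05, gain 1, decay
  0.5 /mm (optical fluence loss with depth), noise SD 0.1 (SNR 10 against
  unit vessel intensity). The moving scan draws an independent noise
  realisation and a log-normal gain jitter (σ = 0.15), emulating
  scan-to-scan technical variability.
* **Biological variability**: a fraction (default 0.1) of terminal segments
  is dropped from the moving network and new terminal sprouts (default 2)
  are added — perfusion loss/gain at the capillary end. Only terminals
  whose parent keeps another child are dropped, so deeper branch points
  survive as landmarks; each pair requires ≥ 3 shared branch points.
* **Ground truth**: rigid transforms rotate about the depth axis (scan-head
  repositioning) with bounded 3D translation (default ±200 µm in-plane,
  ±20 µm in depth); smooth deformable fields are Gaussian-filtered white
  noise (correlation scale 200 µm) scaled so the median displacement is
  half the amplitude (default 40 µm) and clamped at the amplitude — a
  stand-in for week-scale tumour growth. Landmarks transform exactly with
  the ground truth, so pre-noise TRE is identically zero under it.

What passing phantom tests does **not** show: robustness to reflection and
shadow artefacts, limited-view reconstruction errors, melanin absorption, or
real vascular topology; those require real data.

## Pre-processing

The canonical chain is high-pass → Wiener → rolling ball → clip+z-score.
The high-pass is a brick-wall FFT filter along depth (default cutoff 0.01 ×
Nyquist; the low-frequency echo component is removed, everything above
passes with unit gain). The Wiener filter is the classical per-slice
adaptive form with a 3×3 window and the slice-mean local variance as the
noise power. Rolling-ball background removal is implemented as greyscale
opening with a flat disk (radius 5 px) per slice. Percentile clipping
(0.05–99.95) is computed volume-wise; z-scoring is slice-wise (ε = 1e-12
guards constant slices), giving vessels equal weight across depth where
fluence has decayed.

## Affine registration

Both intensity metrics are maximised by plain gradient ascent over a
6-parameter rigid transform (optional 12-parameter affine) about the volume
centre, with central finite-difference gradients (1 µm translation steps,
0.001 rad rotation steps). Because translations (µm) and rotations (rad)
are incommensurate, the optimiser takes normalised-gradient steps of
physical length `learning_rate × initial_step_um` (default 1.0 × 40 µm) in
a µm-equivalent parameter space (rotations scaled by the in-plane
half-extent arm). Step halving within an iteration only guards divergence;
the learning rate never increases. Stopping follows the printed rules: 100
iterations, or an accepted improvement below 1e-8 (no improving step at any
halving also terminates). The best transform visited is always returned, so
the optimised metric can never end below its initial value.

Numerical choices made for sparse, noisy vascular data (all configurable):

* the metric is evaluated on a fixed, seeded subsample (≤ 40 000 voxels) of
  a signal ROI — the dilated segmentation when available, otherwise a
  threshold-segmented region — because a uniform sample would be dominated
  by background;
* both images are Gaussian-smoothed (σ = 2 voxels) on the metric side only,
  widening the capture range; final warps use the unsmoothed volumes;
* inside the optimiser MI uses linear (partial-volume) histogram binning so
  1 µm steps produce usable gradients; the public `mutual_information`
  keeps the plain binned definition (50 equal-width bins, natural log);
* centre-of-mass initialisation in the pipeline is computed on the
  segmentation masks (or on threshold-masked signal when no segmentation is
  available) — on raw volumes the constant background pulls the centroid
  toward the volume centre regardless of where the vasculature sits, and
  gain/depth weighting biases an intensity centroid.

The benchmark driver initialises per pair the way longitudinal studies do:
repositioning-only (rigid ground-truth) pairs get the signal centre of
mass; longitudinal-analogue (smooth-deformation) pairs get least-squares
rigid alignment of the paired landmarks, applied before affine optimisation
and before deformable inference alike.

## Shape-based registration

Masks are resampled to isotropic resolution at the in-plane spacing (20 µm;
linear for intensities, nearest for masks) before any surface operation.
Surfaces come from marching cubes at iso-level 0.5 with one step per voxel
(the mask is zero-padded so boundary surfaces close); normals follow the
descending gradient and therefore point outward. Point-to-plane ICP matches
each moving point to its nearest fixed point within 200 µm (10 isotropic
voxels), solves the linearised small-angle least squares for the rigid
increment, re-orthonormalises, and repeats up to 1000 iterations; the RMS
point-to-plane residual trace is kept non-increasing by terminating at the
first non-improving update, and convergence is declared below 1e-8 change.
The moving cloud is the source. Distance-map registration feeds exact
Euclidean distance transforms (voxel units; centre lines carry the maxima)
of both masks into the NCC affine machinery with centre-of-mass
initialisation.

## Deformable registration

A 4-level encoder-decoder with skip connections maps the four stacked
channels (fixed intensity, fixed segmentation, moving intensity, moving
segmentation) to a 3-channel DDF. The network, its backpropagation and the
Adam optimiser are implemented directly on numpy so the benchmark runs on a
plain CPU stack. For CPU economy the field is predicted at half resolution
and trilinearly upsampled to the input grid (grid dims must be divisible by
32); the smooth ground-truth fields being learned have correlation lengths
of ~10 voxels, well within the half-resolution representation. The last
layer is He-initialised then scaled by 1e-2 so the initial DDF is near zero.

Training minimises the unweighted sum `L_total = L_img + L_seg + L_BE`:
negative global NCC between fixed and warped moving intensities, the
generalised Dice loss with inverse-squared-volume label weights computed
from the fixed mask, and the bending energy — the mean over voxels of the
squared Frobenius norm of each displacement component's Hessian, by central
finite differences on interior voxels, in voxel units. Gradients flow
through a differentiable trilinear warping layer. Adam uses the standard
moments and learning rate 1e-4, batch size 1. Weak supervision means no
ground-truth transform enters the loss.

Desk-scale defaults replace full-scale settings: 64³ isotropic (20 µm)
phantom crops and 50–200 epochs instead of 512 × 512 × 128 crops and 1000
epochs; z-rotation augmentation (up to π/15 rad) is implemented but off by
default at desk scale. The model state with the best validation loss is
returned (without a validation split the epoch-mean training loss doubles
as the selection criterion); a 50/50 split utility is provided.
Deterministic for a fixed seed up to BLAS reduction order. In the benchmark
driver the deformable method is applied after rigid pre-alignment (COM or
landmarks, as above), and is trained (weakly supervised) on the pre-aligned
benchmark pairs themselves when no model is supplied.

## Quality metrics and statistics

Dice is voxel overlap. MD/HD use border voxels under 6-connectivity on the
isotropically resampled grid as the surface definition and report physical
µm; MD pools both directed sums over the combined surface count and HD is
the maximum of the two directed maxima (true maximum, not a percentile).
MI between registered volumes uses the 50-bin histogram definition (nats).
SSIM uses the two-term luminance/contrast-structure form with C1 = (0.01 L)²
and C2 = (0.03 L)², L the dynamic range of the fixed image, over a 7³
uniform window (whole-volume statistics available for closed-form checks).
TRE is the mean Euclidean distance over paired landmarks (µm). Percent
change is `100 · (post − pre) / |pre|`, so the sign is interpretable even
for negative-valued pre metrics: positive is an improvement for
Dice/MI/SSIM and a worsening for MD/HD/TRE.

Method pairs are compared per metric with two-sided Wilcoxon signed-rank
tests on pair-matched percent changes (exact null for n ≤ 15 without ties,
normal approximation with tie correction otherwise; zero differences
dropped; identical samples report p = 1), followed by Holm–Bonferroni
step-down adjustment with m = 10 (the C(5,2) comparisons among five
methods) at α = 0.05.

## Problem sizes used by the test-suite and acceptance script

* Metric-oracle equivalence: ≥ 100 random masks/fields at ≤ 12³ voxels.
* Rigid recovery: 20 seeded pairs at 128 × 128 × 64 (20 × 20 × 4 µm),
  translation ≤ 200 µm per in-plane axis (≤ 20 µm in depth), rotation ≤ 10°
  about depth, SNR 10.
* Deformable training: 4 training + 1 held-out smooth pairs at 64³
  isotropic, COM pre-aligned, 100 epochs, fixed seed.
* Full benchmark: 12 pairs (6 rigid + 6 smooth-deformation) at 64³
  isotropic across all five methods; the deformable model is trained for 60
  epochs on the pre-aligned benchmark pairs themselves.

## Known limitations

* The deformable network is far smaller and far shorter-trained than a
  production registration network; it demonstrates the training machinery
  and the qualitative ranking, not attainable accuracy.
* Global NCC is used as the image loss exactly as printed; windowed/local
  NCC variants often train better on sparse data but are out of scope.
* ICP accuracy under biological variability (dropped/added vessels) is
  limited by the changed surface itself; the sub-0.5° recovery contract
  applies to structurally identical surfaces.
* No reflection-artefact physics, motion, or reconstruction modelling.
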