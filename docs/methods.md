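# Methods

## Problem and model

`synct` learns a mapping from non-contrast cardiac CT (NCT) to
contrast-enhanced appearance (SCECT) with a conditional GAN and then
asks the question that matters clinically: *are contours drawn on the
synthetic image good enough for substructure dosimetry?* The package
therefore couples the generative model to a three-stage validation
(image quality, contour geometry, dosimetry) and to a synthetic-data
module that supplies paired volumes with known truth.

### Generator

A 2-D fully convolutional DenseNet operating on axial slices:

- stem 3×3 convolution (48 features);
- five encoder stages, each a dense block (BN → ReLU → 3×3 conv →
  dropout per layer, growth-rate concatenation) followed by a
  transition down (BN → ReLU → 1×1 conv → dropout → 2×2 max-pool);
  the full dense-block output is kept as the skip path;
- a bottleneck dense block;
- five decoder stages, each a stride-2 3×3 transposed convolution on
  the preceding block's newly produced feature maps, concatenation
  with the matching skip, and a dense block;
- a final 1×1 convolution with tanh onto the normalized intensity
  range.

Default depths are 4/5/7/10/12 layers per encoder stage (mirrored in
the decoder) with a bottleneck of 15 and growth rate 12. These depths
were calibrated so the built network carries 5.4 M trainable
parameters; the matching PatchGAN below carries 1.6 M. Five
down/up transitions mean the input sides must divide 2⁵ = 32;
`preprocess.pad_to_multiple` pads symmetrically at inference.

### Discriminator

A PatchGAN over two-channel (NCT, candidate) pairs: a 4×4 stride-2
convolution (48 features, LeakyReLU), three further stride-2
convolutions doubling the width (with BN), and a final 4×4 convolution
with sigmoid producing a patch map of real/fake scores in [0, 1]. Real
pairs concatenate the NCT with the CECT, fake pairs with the detached
SCECT.

### Objective and schedule

Generator loss = non-saturating adversarial term (BCE of the fake
patch map against the real label) + λ·L1(pred, target) with λ = 100,
so training is close to supervised regression with an adversarial
regularizer; the L1 component equals `image_quality.mae` on the same
tensors exactly and both components are logged separately. The
discriminator minimizes BCE(real, 1) + BCE(fake, 0). Clinical-scale
defaults: batch 4, Adam (β = 0.5/0.999) at 2·10⁻⁴ for G, SGD at
2·10⁻⁵ for D, 200 epochs, checkpoint = lowest validation L1. Labels
are hard (real = 1, fake = 0), no smoothing.

### Numerical engine

The networks run on `synct.nn`, a reverse-mode autodiff tape over
NumPy float32 arrays with im2col-based convolution and transposed
convolution, max-pooling, batch normalization (running statistics are
part of the checkpoint state) and dropout. Convolution backward
recomputes the im2col buffer instead of retaining it, and intermediate
gradients are freed eagerly during backprop — without these two
choices a deep dense network does not fit in desk-scale memory. All
gradients are verified against central finite differences in the test
suite; a global gradient-norm clip of 1.0 on the generator prevents
the occasional late-training collapse of the adversarial game.

## Preprocessing

Resampling is trilinear to 0.9 × 0.9 × 1.0 mm (output shape
`round(extent/spacing)`, origin kept at the first voxel center). The
heart ROI (default 384 × 384 × 150 voxels) is centered on the
heart-mask centroid when a mask is available, else the volume center.
Intensities clip to the [−150, 500] HU contrast window and map
affinely to [−1, 1]; the mapping is exactly invertible on the clipped
range. During training both members of a pair receive the same random
352 × 352 crop (uniform over valid offsets); no other augmentation.
Evaluation-time inference uses full slices without random cropping.
Voxel convention everywhere: 0-based indices, world position = voxel
center, half-open ROI boxes, axis order (x, y, z) with z axial.

## Synthetic phantoms

`phantom.simulate_pair` builds an elliptical torso with two low-HU
lungs and a four-chamber heart: an ellipsoid (semi-axes proportional
to the grid extent) whose interior (ρ ≤ 0.8) is split by two curved
septal surfaces into LV/RV/LA/RA, wrapped in a myocardial shell. The
LAD runs down the anterior left-ventricular surface and the RCA along
the right atrioventricular groove, both as 2.5 mm-radius tubes around
deterministic splines parameterized by the heart ellipsoid; an
ascending great-vessel stub completes the blood pool. Tissue
baselines: body +40, lung −750, myocardium +40, blood +45 HU; the
CECT member adds 150 ± 50 HU (uniform per-sample jitter) to every
blood-pool voxel, emulating protocol heterogeneity, and both members
carry independent Gaussian noise (σ = 10 HU). All values are
configuration, chosen so windowing never clips enhanced blood. The
geometry is deterministic; randomness enters only through
`(seed, sample index)`, so identical configurations reproduce
bit-identical samples.

The dose module emulates (not plans) a tangential breast field: full
prescription (40 Gy) inside a wedge over the chosen chest wall,
exponential falloff with a 20 mm length outside it, mirrored for
right-sided or bilateral fields. The default left-sided geometry
yields a mean heart dose of ~2.7 Gy, in the range typical of
tangential plans.

What the phantoms deliberately do **not** contain: anatomically
realistic (XCAT-grade) shape variation, cardiac or respiratory motion,
beam-model physics, or inter-patient anatomy differences (the anatomy
is identical across samples; only noise and enhancement vary). A model
that passes the phantom suite has demonstrated that the pipeline
wiring, losses, metrics and dosimetry are correct and that the
translation task is learnable — not that it generalizes across real
patients.

## Validation stages

**Image quality** is computed slice-wise on the clipped-HU scale with
MAX_I = 650 (the window width) — the scale and MAX_I choice are
recorded in every report header, since results are not comparable
across scales. PSNR of identical slices is reported as a +∞ sentinel
and excluded from means with a count, never clamped. SSIM uses the
original 11×11 Gaussian window (σ = 1.5, k1 = 0.01, k2 = 0.03),
averaged over fully interior window positions; the implementation is
oracle-tested against explicit window loops and cross-checked against
scikit-image. Arms are compared with a two-sample equal-variance
t-test (Welch by flag).

**Contour geometry** uses a single voxel model end to end: rasterized
contours include a voxel when its center is inside the polygon
(even-odd rule, so holes work); surfaces are mask voxels with a face
neighbour outside (volume boundary counts as outside); MSD is the
symmetric mean of center-to-center nearest distances, computed by
Euclidean distance transform with anisotropic sampling and validated
to 10⁻⁹ mm against an all-pairs oracle. The 5 mm vessel margin is
applied to *both* structure sets before DSC/MSD and before dosimetry,
because the margin is part of the delineation protocol. Empty-vs-
nonempty comparisons score DSC 0 with MSD flagged undefined.

Because no human rater exists at desk scale, "contouring on the
synthetic image" is emulated: truth masks are warped by a smooth random
displacement field whose RMS amplitude is proportional
(0.04 mm per HU) to the local mean absolute error of the generated
volume around the structure. A perfect SCECT reproduces the truth
contours exactly; a poor one drifts — the same direction of effect a
human rater would show, without claiming to model rater behaviour.

**Dosimetry** resamples dose trilinearly onto the CT grid (never masks
onto the dose grid), counts whole voxels, uses inclusive thresholds
for V_t, takes D_max as the maximum voxel dose (not D0.03cc — recorded
in report metadata) and D_mean as the arithmetic voxel mean. DVHs use
0.01 Gy bins, start at 100% and end at zero. The same transferred dose
field is applied to both structure sets of a case (plan-transfer
design; no re-optimization), so reported differences isolate the
contouring effect.

## Desk-scale study conditions

CPU-scale runs (demo pipeline, learnability checks) use 8 phantoms of
64 × 64 × 32 voxels at 2.5 × 2.5 × 3.0 mm, split 5/1/2
(train/validation/test, the clinical 35/4/20 proportions), training on
32 × 32 heart-ROI slices — the in-plane ROI crop mirrors the clinical
crop-near-heart step and concentrates the L1 signal on cardiac tissue.
The small network config is 2 layers per dense block, growth 8, stem
16, no dropout, with an 8-feature discriminator. The desk schedule
(`cgan.desk_train_config`) raises the generator learning rate to
2·10⁻³ with Adam β₁ = 0.9 and decays it linearly over the second half
of training: a ~100 k-parameter network both tolerates and needs a
larger step size than the 5.4 M clinical configuration, and the decay
keeps the adversarial game stable in late epochs. Learning the
enhancement requires distinguishing blood (+45 HU) from myocardium
(+40 HU) — a 5 HU contrast, ~1.5% of the window — which is the hard
part of the task at any scale and the reason the schedule matters.

## Degenerate inputs and tie-breaks

Empty structure sets raise; empty single masks are flagged, not
raised. DSC of two empty masks is defined as 1 with a degenerate flag.
Contour planes must lie within half a slice spacing of a grid slice.
Dose resampling outside the source grid yields 0 Gy with a coverage
warning; zero overlap raises. Max-pooling breaks ties by first index.
t-tests over zero-variance cohorts return p = 1 (identical) or p = 0
(different constants) rather than NaN.

## Known limitations

- The phantom anatomy is deterministic across samples; generalization
  across anatomies is untested by design.
- Slice-wise 2-D generation can produce through-plane inconsistency
  that a 3-D generator would not; the validation stages would surface
  it as elevated MSD, but no explicit through-plane regularizer
  exists.
- The simulated-contouring model is a calibrated stand-in for human
  delineation variability, not a model of it.
- The NumPy engine is single-threaded (BLAS aside); clinical-scale
  200-epoch training is out of its intended scope.
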