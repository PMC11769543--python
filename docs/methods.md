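# Methods

## The problem and the model

Renal cell carcinoma appears in contrast-enhanced CT as a mass within or
protruding from the kidney, often hypodense relative to the enhancing
parenchyma and hard to find when small (T1a, <= 4 cm). Single networks
that segment the whole abdomen at once see an enormous search space and
produce false positives on distant bright or textured structures
(vertebral bodies, bowel). The framework here is coarse-to-fine:

1. **Stage one** segments the kidney *organ* on the preprocessed volume.
   The two largest 26-connected components of the binary mask (left and
   right kidney) give tight bounding boxes; each box is expanded by 25 %
   of its extent per axis (12.5 % per side, clipped to the grid) into a
   volume of interest (VOI). The expansion supplies perirenal context and
   covers exophytic tumor growth beyond the organ surface.
2. **Stage two** segments *tumor* voxels only inside the VOIs. Predictions
   from overlapping VOIs merge by voxelwise maximum probability before
   thresholding at 0.5. Tumor voxels outside every VOI are impossible by
   construction — the single-stage failure mode is removed structurally,
   not statistically.

Tumor masks are binary within the VOI; tumors are not constrained to lie
inside the kidney *mask* (exophytic lesions extend beyond the organ), only
inside the expanded VOI.

### Networks

*Organ backend (default, "swin")* — a shifted-window transformer encoder:
a strided patch-embedding convolution, then four steps of two
window-attention blocks each (window 7 per axis by default, alternating
unshifted/shifted by half a window), patch-merging convolutions doubling
width between steps; a CNN decoder of residual blocks with instance
normalisation, deconvolution upsampling and a pointwise convolution +
sigmoid head. Two simplifications relative to full Swin attention: no
relative position bias, and no attention mask for tokens wrapped by the
cyclic shift — at phantom scale both are second-order effects. A small
residual-UNet backend ("cnn") is the CPU-scale drop-in; stage one is a
pluggable interface and the comparison of backbones is itself part of the
framework's purpose.

*Kidney Tumor 3D UNet (stage two)* — six encoder stages of residual
blocks, widths (32, 64, 128, 256, 320, 320), block counts
(1, 3, 4, 6, 6, 6); stage 6 is the bottleneck, so five 2x downsamplings
take the default 192 x 128 x 128 patch to 6 x 4 x 4. Downsampling is a
strided convolution inside the first residual unit of each stage. The
decoder mirrors the encoder with one 3x3x3 convolution per stage after
deconvolution upsampling and concatenation with the attention-gated skip.
The attention gate is additive: skip and (upsampled) gating features are
projected pointwise to a common width, summed, passed through LeakyReLU,
projected to one channel and squashed by a sigmoid; the resulting
per-voxel coefficients multiply the skip features. Gating signals come
from the decoder side. LeakyReLU (slope 0.01) and instance normalisation
are used throughout; no deep supervision; the head is a pointwise
convolution + sigmoid over one tumor channel.

### Preprocessing and augmentation

Pooled over the training set: clip to the [0.5, 99.5] percentile window
(linear interpolation between order statistics), resample isotropically to
1.0 mm (trilinear images / nearest-neighbour masks, extents
`round(n * spacing / target)`, round half away from zero), z-score with
the pooled post-clip mean and SD. The four numbers are frozen into the
model checkpoint so inference reproduces training normalisation exactly.
Per-volume statistics are available behind a flag for ablation.

Augmentation: random rotations (±30° per axis, p 0.3), scaling
(0.85–1.25, p 0.3), mirroring (p 0.5 per axis), in-plane transposition
(p 0.2), gamma correction (0.7–1.5, p 0.3, image only, min-max
renormalised). The transform families are fixed; all magnitudes are
config. Geometric transforms resample on the fixed grid, padding with the
volume minimum.

### Training

DiceCE loss: `(1 - soft Dice) + BCE`, both averaged over the patch, with
probability clamping at 1e-7 and smoothing 1e-5 in the Dice term. Patches
are sampled with a configurable fraction centred on a random foreground
voxel (default 0.5; 0.6 in the desk study — small-lesion sensitivity
requires foreground-biased sampling). Polynomial learning-rate decay
(power 0.9) over the full run.

Full-scale defaults: AdamW (lr 3.5e-4,
decoupled weight decay) for the organ stage, SGD (lr 0.001, nesterov
momentum 0.99) for the tumor stage, batch 5, patch 192 x 128 x 128. The
**desk-scale study** (what the tests and `scripts/acceptance.py` run)
deviates deliberately:

* tumor nets are 3-stage (widths 8/16/32, blocks 1/2/2), patch 32³,
  batch 2 — sized to the ~24–34-voxel VOI crops of 64³ phantoms; the VOI
  net trains 10 epochs over the ~80 crops, the single-stage comparator 25
  epochs over 20 whole volumes (comparable step counts);
* the organ net is the CNN backend (widths 8/16/32) trained on 48³ crops
  of the 64³ volumes (batch 2, 30 epochs, AdamW lr 3e-3) with a matching
  48³ inference window — near-whole-volume context at 40 % of the compute
  of full 64³ training, and no train/inference shift in the instance-norm
  statistics;
* the tumor stages also use AdamW (lr 3e-3, weight decay 1e-4). At a few
  hundred optimisation steps, SGD at lr 0.001 with
  heavy momentum demonstrably remains in the empty-prediction minimum of
  the DiceCE landscape (the network outputs max probability ~0.13 and
  zero Dice); AdamW escapes it reliably. SGD stays the default for the
  full-scale preset, where run lengths are orders of magnitude longer.

The numpy engine runs single-sample forward/backward passes with gradient
accumulation over the mini-batch; with a fixed seed and single-threaded
BLAS, training is bit-reproducible run to run. Convolutions execute as
numba-compiled direct kernels (with `fastmath`, which fixes a different
but still deterministic summation order) below 2048 in*out channels, and
as per-offset BLAS matmuls above; every backward pass is validated against
finite differences in the test suite.

### Kidney mask postprocessing

`segment_kidney` fills interior holes of the thresholded mask by default.
A hypodense intrarenal tumor looks like soft tissue, so an organ network
trained on few examples tends to punch a hole where the tumor sits; the
kidney organ is simply connected, making hole-filling a property of the
anatomy rather than a tuned heuristic. Exophytic portions are recovered by
the 25 % VOI expansion instead.

Short training runs also leave the sigmoid head poorly calibrated, so the
desk study sweeps the organ probability threshold (0.3–0.8) on a handful
of *training* volumes after training and freezes the best value into the
pipeline configuration. The sweep corrects a property of the model rather
than of any image — measured threshold curves on training and held-out
volumes coincide to three decimals — and costs one inference pass per
calibration volume. The pipeline default remains 0.5 when no calibration
is run.

## Evaluation protocol

Voxel scores per matched instance: Dice, precision, volumetric distance
VD = |FN−FP|/(2TP+FP+FN), over-/under-segmentation ratios OSR = FP/(TP+FN),
USR = FN/(TP+FN). Degenerate conventions: empty reference *and* empty
prediction scores Dice 1 and VD = OSR = USR = 0; empty reference with a
non-empty prediction leaves OSR undefined (reported as infinity).

Detection: tumor instances are 26-connected components (components under
8 voxels discarded as noise); predicted instances match reference
instances greedily in descending object-IoU order, one-to-one, accepting
matches at IoU >= 0.25. Unmatched predictions are false positives; FPC is
their count averaged over patients, binned by the false positive's own
measured diameter (a false positive has no reference size).

Size: the unidirectional diameter (UD) is the largest voxel-centre
distance within any single axial slice, floored at one in-plane voxel
extent (so an isolated voxel measures one voxel across; a discretised
disk of radius 15 voxels measures exactly 3.0 cm). A 3-D maximal Feret
diameter is flag-selectable. Bins: small <= 4 cm < medium <= 7 cm < large,
with small sub-bins at 2 and 3 cm. Per-category Dice is reported over
detected tumors by default ("detected-only"); a mode counting missed
tumors as Dice 0 is available.

Paired model comparison uses the two-sided Wilcoxon signed-rank test on
per-case Dice (exact distribution at small n; identical lists return
p = 1 as there are no signed ranks).

Evaluation runs on the 1.0 mm processing grid by default; predictions are
also resampled back to the native grid (nearest neighbour) and a flag
selects native-grid evaluation.

## The phantom generator

Each case paints analytic geometry on the voxel grid (inside-ellipsoid
tests at voxel centres — exact ground truth, no meshing): an air
background (−1000 HU), a soft-tissue body ellipsoid (40 HU), two kidney
ellipsoids (120 HU, emulating enhanced parenchyma), a high-density spine
cylinder (700 HU) posterior to the kidneys as a false-positive decoy, and
spherical tumors attached to a kidney — intrarenal or exophytic (centred
on the organ surface) — with radius set from the requested UD and
intensity `kidney − offset`. Gaussian noise is added last. Difficulty
regimes: *easy* = 60 HU tumor contrast, 10 HU noise; *hard* = 20 HU
contrast, 25 HU noise — chosen so that a tiny CPU-trained model separates
the regimes reliably. Grid presets: `abdomen` (96 x 96 x 48 at
1.5 x 1.5 x 3.0 mm — anisotropic to exercise resampling, large enough for
tumors to 8.5 cm) and `desk` (64³ at 1 mm, small tumors, sized for CPU
training). The default cohort size mix (54 % small / 24 % medium / 22 %
large) mirrors a public kidney-tumor cohort.

What the phantoms do *not* emulate: CT physics (beam hardening,
reconstruction kernels, partial-volume blur), anatomic neighbours other
than the spine, cysts and benign masses, multi-phase contrast dynamics,
and tumor texture heterogeneity. Passing the desk-scale study therefore
demonstrates that the *pipeline machinery* — preprocessing, localisation,
VOI geometry, patch training, blended inference, paste-back, and the
evaluation protocol — is correct and that the dual-stage containment
property holds; it does not certify clinical-grade accuracy on patient
scans.

## The desk-scale study

50 easy phantoms; 40 train / 10 held out; the organ net trains on 10
volumes, the single-stage comparator on 20, the VOI tumor net on all 40
(as ~60–80 VOI crops). Held-out dual-stage performance is summarised by
median kidney and tumor Dice, small-tumor sensitivity and FPC. A separate
12-case *hard* cohort probes false positives: the dual-stage model cannot
emit tumor voxels outside its VOIs (checked exactly), and its FPC is
compared against the single-stage model's. All sample sizes were chosen
to make the full study a matter of minutes on one CPU; every random
stream descends from the single `--seed` argument.

## Numerical choices and degenerate inputs

* Percentiles: linear interpolation between order statistics (tested
  against a sort-based oracle).
* Resampled extents: round half away from zero, minimum 1 voxel.
* Normalisation refuses constant data (SD = 0) rather than dividing by 0.
* Volumes smaller than an inference window are padded symmetrically and
  cropped back; sliding windows overlap 50 % with Gaussian blending
  (sigma 1/8 window, floored at 1e-3 so coverage never divides by ~0).
* An empty kidney mask yields an empty VOI list and an empty tumor mask
  ("no kidney found"), not an error.
* Greedy IoU matching breaks ties deterministically by argsort order;
  optimal assignment differs only in pathological overlap patterns.
* Checkpoints store weights, the full network config and the frozen
  intensity statistics in one `.npz`; a config hash accompanies every
  artifact written by the CLI.

## Known limitations

* The transformer organ backend trains at toy scale in tests but is not
  exercised as the trained stage-one model in the desk study (the CNN
  backend is); at full scale the two are interchangeable behind the same
  interface.
* The engine is single-sample; there is no data or model parallelism.
* Hard-regime sensitivity of the tiny desk models is well below the
  easy-regime value — expected, and used only as an ordering probe.
* The 5-channel softmax / two-class variants of the tumor head are
  config-selectable but the studied configuration is the single-channel
  binary head.
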