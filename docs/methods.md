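# Methods

This note documents the models and procedures implemented in
`fundustruct`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic study does and does
not demonstrate.

## Preprocessing

Fundus photographs have a black camera background whose hard edge
corrupts histogram equalization. The chain is:

1. **Background mask.** Luma gray (`0.299 R + 0.587 G + 0.114 B`) strictly
   above `background_threshold` (default **40** of 255) marks the eye
   region. The strict inequality is deliberate and tested; raising the
   threshold never adds foreground (monotonicity is a property test).
2. **Mean fill.** Background pixels are repainted with the per-channel
   mean of the *foreground* (including the background in the mean would
   drag it toward black, defeating the purpose).  An image with no
   foreground raises a degenerate-input error rather than dividing by
   zero.
3. **CLAHE on L.** sRGB → CIELab (D65, 8-bit scaling); contrast-limited
   adaptive histogram equalization on the L channel only (a/b untouched);
   back to RGB. `clahe_clip_limit` (default **2.0**) is expressed on the
   conventional scale of "multiple of the mean histogram-bin height";
   internally it maps to scikit-image's normalized clip as `clip/256`.
   Tile grid: **8×8**.
4. **Background restore.** Masked pixels are set back to exact (0,0,0).

Rotation augmentation produces every multiple of `step_deg` (default
**10°**, so ×36) per image, 0° included, image-major order. Right-angle
rotations are performed as exact grid permutations (`rot90`), so rotating
four times by 90° is bit-exact; other angles use bilinear interpolation
with black fill. The train/validation split is a seeded uniform draw and
must happen *before* augmentation so no rotation of a validation image
leaks into training.

## Optic-disc extraction

Right-eye discs sit in the temporal (right) half, so the image is first
cropped to columns `[W/2, W)`. The brightest **3.5 %** of CIELab-L pixels
(ties at the percentile threshold all kept) vote in a circular Hough
transform; search radii default to [15, 120] px at 512-row scale (scaled
linearly with raster height, stepped by 2 px).

Two robustness measures, both established on phantom experiments:

- **Morphological closing (radius 3)** of the brightness mask before the
  Hough transform. When the disc holds more pixels than the 3.5 % budget,
  the percentile rule selects a noise-ordered speckle subset of the disc;
  closing solidifies it, while isolated stray bright pixels are erased.
- **Boundary rule.** A filled blob lights every circle it contains, so
  "highest vote" alone often returns an interior circle (especially when
  vessels crossing the disc cut its mask). The detector instead takes
  the *largest* radius whose peak perimeter-normalized vote is within
  `boundary_tolerance` (default **0.85**) of the global maximum — for a
  solid blob that is exactly its boundary circle. If the best vote falls
  below `accumulator_threshold` (default **0.4**), or closing empties the
  mask, the detector falls back to the bright-pixel centroid with the
  area-equivalent radius and records the provenance.

The returned radius is the detected radius plus **40 px**, a safety
margin that keeps the whole disc rim inside the crop. The final crop is
the square bounding box of the extended circle (zero-padded at raster
edges) — cropping to the detected circle canonicalizes disc position and
scale before the 64×64 resize, which is what makes the cup-to-disc
geometry available to a classifier at that resolution; resizing the whole
half-image instead can shrink a small disc to a few pixels.

Disc extraction runs on the *original* photograph (the percentile rule
assumes the camera's native brightness distribution); vessel segmentation
runs on the *preprocessed* one.

## Vessel segmentation

The preprocessed gray image at 256×256 is cut into sixteen 64×64 patches
(row-major 4×4; `stitch(tile(x)) == x` bit-exactly, property-tested), each
segmented independently, stitched, and resized to 64×64. No overlap or
blending — the tiling is exact.

The network is a residual U-Net: encoder residual blocks with filters
**(16, 32, 64)** and 2×2 max-pool between levels, a **128**-filter bridge,
and a mirrored decoder (nearest-neighbor upsampling + convolution, skip
concatenation from the matching encoder level, residual block). Six
residual blocks in total, one skip per level pair. Each residual block is
conv–BN–ReLU, conv–BN, identity shortcut (1×1 projection when channel
counts differ), ReLU. Final 1×1 convolution + sigmoid.

Training defaults: soft-Dice loss, Adam at **5e-4**, batch 8, **15**
epochs, all randomness from one seed. Both defaults are stability
choices: binary cross-entropy stalls near the all-background solution at
the ~6 % vessel-pixel prevalence of the phantoms, and learning rates
around 3e-3 collapse the network to a constant output from roughly half
of the initialization seeds. Per-level filter counts and training
hyperparameters are configurable (`ResUNetSpec`, `VesselTrainConfig`).

## Classifier

Three 64×64×1 inputs — preprocessed image, vessel probability map, disc
crop — pass through structurally identical CNN branches: four 3×3
convolutions (ReLU) with filters **(64, 128, 256, 512)**, BatchNorm +
2×2 max-pool after the second and fourth, output 16×16×512.

**Attention fusion.** The image branch provides queries; each structure
branch provides keys and values; attention is scaled dot-product over the
flattened spatial positions (`softmax(QKᵀ/√d)V`, weights nonnegative and
row-normalized, asserted in tests against a brute-force oracle). The two
attended maps are concatenated (2×512 channels), BatchNorm + max-pooled,
and passed to the head. The query-role assignment is a design choice: the
mechanism is cited in the source architecture without equations, and
letting the full-image features interrogate the structure features is the
minimal wiring in which all three inputs influence the fused map.

**Ablation variant.** The three branch outputs concatenate channel-wise
(3×512) with no attention; the head is identical.

**Head.** Convolutions with filters **(2048, 4096, 4096)**, the last with
a **1×1** kernel; BatchNorm; then *global average pooling* and dense
layers (default 256 → 2) with ReLU on the penultimate layer and softmax
over {glaucoma, normal}. Global pooling rather than flattening is
essential at this data scale: pooled channel statistics are count-like,
translation-tolerant features, whereas a flatten lets a small dataset be
memorized by position (observed as perfect training accuracy with chance
validation accuracy). The flag (`HeadSpec.global_pool`) can be disabled.

Training: Adam at **2e-3**, batch 8, categorical cross-entropy, up to
**20** epochs, seeded. After (and during) training, BatchNorm running
statistics are recalibrated with equal-weighted passes over the training
set — short small-batch trainings otherwise leave the exponentially
averaged statistics far enough from the dataset statistics to distort
eval-mode predictions badly.

The learnability study trains the desk-scale configuration (branch
filters 8/16/32/32, head 32/64/64, dense 64/2); the paper-scale topology
above is exercised structurally (construction, introspection, single
forward passes) but not trained — training ~170 M parameters on phantom
data would add hours without changing what the study demonstrates.

## Evaluation

Per-class sensitivity, precision, F1 (harmonic mean). Ratios with a zero
denominator are reported as NaN with a warning, never silently 0 — a
constant classifier should look broken, not half-right. ROC and AUC (via
scikit-learn's threshold sweep and trapezoidal rule) use glaucoma as the
positive class; a test asserts agreement with an independent
Mann–Whitney pairwise-concordance implementation to 1e-9.

## Phantom generator

Each phantom is a 512×512 right-eye fundus: black outside a circular eye
field (radius 0.47×size); an orange field with a gentle (6 %) radial
vignette and additive Gaussian noise (σ = 3 levels, clipped, applied only
inside the eye so the background stays exactly black); a bright disc
(radius 20–60 px) in the temporal half; a concentric cup whose radius
ratio is drawn from [0.2, 0.4] for normal and [0.7, 0.9] for glaucoma
phantoms; and 6–12 dark random-walk vessel branches (width 2–6 px)
radiating from the disc center, rasterized into the image and into a
binary ground-truth mask. Everything derives from one seed; datasets are
bit-reproducible.

Two deliberate stylizations, both load-bearing for the study design:

- **The cup is rendered dark** (CIELab L below the field) rather than as
  a pale region slightly brighter than the disc rim, as in real
  photographs. This serves two purposes. The brightness mask then sees
  the disc as a bright annulus whose outer boundary is exactly the disc
  radius, so disc detection is well-posed across the whole radius range
  even when the disc exceeds the 3.5 % pixel budget. And the class signal
  becomes a contrast between well-separated intensity bands, which a
  small CNN can learn from ~50 images; with a subtle bright-on-bright
  cup the phantom classes are still separable in principle but not
  learnable at this data scale, which would make every classifier test
  meaningless.
- **A thin bright rim annulus** (flash-reflection analogue, L between
  field and disc) near the eye boundary absorbs whatever part of the
  brightness budget the disc does not use. Without it that surplus lands
  on the smoothly-shaded field center as a compact blob that can host a
  spurious Hough circle.

A property test guarantees the signal is real: a hand-written scalar
feature (dark-pixel share of the disc crop) must separate the classes
with ≥ 0.9 accuracy before any CNN result is taken seriously.

## What the synthetic study shows — and does not

The study (32 phantoms per class, 24/8 train/validation per class)
demonstrates that the pipeline is *correctly plumbed and learnable*:
disc recovery to a few pixels, vessel Dice ≈ 0.85 on held-out phantoms,
and both fusion modes reaching high validation accuracy and AUC on the
cup-to-disc signal. It does not demonstrate clinical performance: the
phantoms lack camera variation, pathology other than the cup/disc
geometry, texture, and the label noise of real datasets; on phantoms the
geometric signal is strong enough that the ablation variant performs as
well as the attention model, so the study cannot arbitrate between
fusion modes — it only verifies both train and evaluate correctly.

## Numerical and engineering notes

- All networks run on `fundustruct.nn`, a small reverse-mode autograd
  over float32 numpy arrays (im2col convolutions, fused pooling/upsample
  primitives, Adam). Gradients are verified against central differences.
- Max-pool gradient ties are broken to the first maximum per window, so
  backward passes are deterministic.
- Training is bit-reproducible given a seed (single-threaded numpy BLAS);
  tests assert identical loss histories and weights across reruns.
- Degenerate inputs fail loudly: empty brightness mask, all-background
  images, single-class training sets, and malformed label tables all
  raise typed errors with the offending quantity named.
- Problem sizes in the test suite and acceptance script (32 phantoms per
  class, 64 training patches, 15/20 epochs, reduced filter counts) were
  chosen as the smallest sizes at which every stage's behavior is
  unambiguous; they run in minutes on one CPU core.
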