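# Methods

This note documents the models, conventions and numerical choices behind
`beadspot`, and what the synthetic benchmark does and does not show.

## Problem setting

The object of interest is a field of sub-resolution fluorescent beads imaged
at 2–4 px diameter in a single grayscale channel.  The task is instance
counting, not segmentation: report one center per bead, including beads that
touch.  At native resolution two touching beads' centers can occupy adjacent
pixels, so no per-pixel labeling can keep them apart; after integer-factor
bilinear upsampling the centers separate and each bead can be marked by a
small disjoint "seed" block.  Detection then decomposes into semantic
segmentation of seeds followed by connected-component counting.

## Coordinate and upsampling conventions

All coordinates are 0-based `(row, col)` with pixel centers on integer
coordinates; sub-pixel centroids are allowed everywhere.

Upsampling by integer factor `f` uses *pixel-area alignment*: original pixel
`c` corresponds to the block `[f·c, f·c + f − 1]` of the upsampled grid, so
the block center sits at `f·c + (f − 1)/2`, and an upsampled pixel `y`
samples the original image at `(y − (f − 1)/2)/f`, clamped at the borders
(edge replication for the outer half-pixel band).  This convention, rather
than corner alignment, is what makes a 2×2 seed block land symmetrically on
an integer original centroid; it matches the half-pixel convention of most
image-resizing libraries.  The implementation evaluates the interpolant
explicitly on this grid (`scipy.ndimage.map_coordinates`, order 1) so the
convention is exact and testable against the closed-form formula.

The default factor follows the bead-diameter rule `f = ceil(8 / d_min)`,
giving 4 for 2-px beads: upsampled bead diameters of ≥ 8 px leave room for
disjoint 2×2 seeds between neighbours.

Seed blocks are placed at the `seed_size × seed_size` block whose center is
nearest the mapped centroid, ties toward smaller indices.  For factor 4 and
integer original centroid `(r, c)` this sets rows `{4r+1, 4r+2}` × cols
`{4c+1, 4c+2}`.  Two beads whose original centers differ by at least 1 px
always produce 8-disjoint seeds (property-tested); the optional cross
dilation (3×3 plus-shaped structuring element) enlarges each seed from 4 to
12 px and can merge the seeds of beads about 1 px apart — which is why both
label variants are trained and compared.

## Synthetic scenes

The generator emulates low-resolution bead assays so the whole pipeline is
testable without external data.  Defaults (chosen once, as the study
conditions):

| parameter | default | rationale |
|---|---|---|
| image size | 32 × 32 px | typical analysis tile for this magnification |
| beads per image | 26 | ~2600 beads per 100 images, realistic assay density |
| bead diameter | U(2, 4) px | the stated sub-resolution regime |
| touching fraction | 0.2 | a fifth of beads placed 1–2 px from a neighbour |
| peak amplitude | U(0.4, 0.9) | varied brightness above background |
| background | 0.1 | offset typical of fluorescence backgrounds |
| read noise σ | 0.05 | moderate noise, SNR ≈ 8–18 |
| shot noise | off by default | `poisson_scale > 0` enables it |

Each bead is an isotropic Gaussian with FWHM equal to the nominal diameter
(σ = d/2.3548) and peak amplitude at the centroid — the standard
diffraction-limited spot approximation.  Isolated beads keep ≥ 3 px center
separation; "touching" beads are placed at U(1, 2) px from an anchor.  Beads
whose nominal extent (d/2) crosses the border are generated but flagged as
not fully visible, and are excluded from the annotation used for training
and scoring — as in manual annotation practice, where a partially visible
bead cannot be annotated reliably.

What the generator does **not** model: optical PSF tails beyond the Gaussian
core, intensity bleed-through between channels, uneven illumination, camera
fixed-pattern noise, clustered/occluded 3D bead stacks.  Passing the
synthetic benchmark therefore shows that the pipeline resolves touching
Gaussian spots under moderate noise; it does not certify performance on any
particular microscope's data, for which retraining on annotated crops is the
intended route.

## Detector

A compact U-Net: `depth` encoder levels (default 3) of two 3×3
convolution + batch-norm + ReLU layers each, 2×2 max-pooling, a bottleneck,
nearest-neighbour 2× upsampling with skip concatenation in the decoder, and
a 1×1 convolution producing one logit per pixel.  The head bias is
initialized to −4 because seeds cover well under 1 % of pixels; starting at
the foreground prior shortens the initial phase in which the network only
calibrates its output rate.

The loss is the sum of pixel-mean binary cross-entropy and smoothed Dice
loss `1 − (2Σpt + 1)/(Σp + Σt + 1)` (smoothing 1, probabilities clamped to
[1e−7, 1−1e−7]).  BCE alone stalls on extremely unbalanced targets; the Dice
term supplies a gradient proportional to overlap regardless of class
imbalance.  Gradients are taken with respect to logits in closed form and
verified against finite differences in the tests.

Training uses Adam (lr 3e−3 by default) with cosine decay to zero over the
run, batches of random crops (`input_size`, default 128 px at upsampled
resolution; when crops are smaller than the images, each image contributes
`crops_per_image` crops per epoch, multiplying optimizer steps at constant
cost), and online augmentation: horizontal/vertical flips, 90° rotations
(image and mask), multiplicative gain U(0.8, 1.2) and additive Gaussian
noise with σ up to 0.05, image only.  Gaussian-blur augmentation exists in
the configuration but is **off by default**: blurring at the scale of the
inter-seed gap erases the intensity dip that separates touching beads, and
measurably increases misses on close pairs; it is intended only for
adapting to genuinely out-of-focus data.  The checkpoint with the best
validation loss is kept; validation runs every second epoch because a
full-resolution validation pass costs about as much as an epoch of
crop-level steps.

The layer stack is implemented directly over NumPy (im2col convolutions in
channels-last layout feeding BLAS matmuls, explicit backward passes, Adam).
At this model scale (10⁴–10⁶ parameters, images a few hundred px across)
this trains in minutes on one CPU core, has no framework dependency, and is
bit-deterministic for a fixed seed — which the reproducibility tests rely
on.

### Model zoo and selection

Neither label variant (plain vs cross-dilated seeds) dominates: dilation
reduces misses on isolated beads but can merge labels of very close pairs.
`train_zoo` therefore trains `n_inits` random initializations per variant
(distinct seeds derived from the master seed) and `select_model` runs the
full inference + evaluation pipeline per candidate, picking the best
detection F-score; ties break toward fewer added detections, then lower
index.  Selection uses the validation split by default to keep the test
split untouched; selecting on the test split is available as an explicit
option (`--select-on test`) for mimicking benchmark protocols that pick the
best test model.

## Post-processing

Predictions are binarized at a global threshold of 0.5 (strict `>`, so
exact-0.5 pixels are background), labeled with 8-connectivity, and each
component contributes its unweighted mean pixel coordinate as one detected
bead.  With 4× upsampling, undilated seeds of adjacent beads keep a 2-px
gap, so the connectivity choice cannot merge them.  A minimum component size
is exposed but off by default.  No watershed-style splitting of merged
components is attempted: separability is the upsampling's job.

## Evaluation scheme

Ground-truth seeds are enlarged to squares of side `2·halfwidth + 2`
(default halfwidth 3 → 8×8, i.e. the upsampled extent of a 2-px bead)
centered on each seed; overlapping squares are partitioned by nearest
centroid (ties to the lower bead index).  Each predicted centroid, rounded
to the nearest pixel, is credited to the region containing it:

* bead with 0 credited seeds → **missing**;
* bead with ≥ 2 → **split** (each seed beyond the first counts as one false
  positive);
* prediction in the background → **added**, unless it lies within
  `border_margin` px of an image edge, in which case it is ignored (the
  border correction: partially visible border beads are not annotated, so
  predictions there cannot be scored either way).

With TP = beads credited at least once, FP = added + split surplus, FN =
missing, the report carries `Q_P`, `Q_R`, `Q_F`, the three rates as % of
ground-truth beads, and total detections %.  These definitions reproduce the
published three-decimal metric values of the deterministic reference
detectors exactly from their aggregate error counts (tested), and satisfy
`detections = 100 − Q_miss + Q_add + Q_split` whenever every split bead has
exactly two seeds.

Multi-image evaluation pools match tables (micro-average) before computing
one report; the tests include a counterexample showing this differs from
averaging per-image metrics.

The default border margin (4 px, the enlargement extent) matches the general
convention; for the synthetic benchmark the margin is derived from the
generator's annotation rule instead — beads whose center lies within
`d_max/2` of the edge may be unannotated, so the experiment uses
`factor · d_max/2` (= 8 px for 4× and 4-px beads).  With the smaller margin,
correct detections of real but unannotated border beads would be charged as
false positives.

## Baselines

* **LoG seeding** — scale-normalized `−σ²∇²G` responses at three scales with
  σ = d/(2√2) spanning the diameter range, maximized over scale; regional
  maxima above a relative threshold (default 0.1 of the global maximum),
  greedy non-maximum suppression at `min_distance` (default: the minimum
  diameter).  Only the seed-detection stage of LoG-based spot pipelines is
  implemented, as that is the stage being compared.
* **Circular Hough** — Sobel gradients; edge pixels above the Otsu threshold
  of the gradient magnitude vote at `radius` px along their gradient
  direction for each integer radius in the range; accumulators are smoothed
  (σ = 1), maximized over radius, peaks above a sensitivity fraction
  (default 0.5) suppressed at `min_distance`.
* **Otsu + EDT** — global Otsu threshold (256-bin between-class variance,
  implemented in-package and cross-checked against exhaustive search and
  `skimage`), Euclidean distance transform of the foreground, regional
  maxima within the foreground at `min_distance` separation; any foreground
  component left without a detection contributes its centroid.  Its
  characteristic failure — merging touching beads — is exactly the regime
  the learned pipeline targets.

Local maxima are plateau-aware regional maxima (8-connectivity); a plateau
contributes its lexicographically smallest pixel, making all baselines
deterministic.

## Desk-scale benchmark sizes

The end-to-end experiment in the test suite uses the generator defaults
(60/15/25 images of 32×32 px) and trains a zoo of 2 + 2 models with
`base_channels=12`, 64-px crops, 4 crops per image per epoch and 24 epochs —
about 1400 optimizer steps per model, a few minutes each on one CPU core.
These sizes are the package's benchmark configuration; larger models and
longer schedules only improve the margin.

## Known limitations

* Bead pairs much closer than ~1 px remain genuinely ambiguous — a slightly
  elongated bright blob could be one large bead or two small ones — and
  dominate the residual misses.
* The evaluation is purely region-membership based; localization error in px
  is not scored.
* 2D only; no multi-channel logic (e.g. inside/outside-cell bead
  classification) and no 3D stacks.
* The NumPy training loop is single-threaded and CPU-bound; it is meant for
  desk-scale models, not for large-scale GPU training.
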