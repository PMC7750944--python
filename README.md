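# beadspot

Detection and counting of sub-resolution fluorescent beads in low-resolution
microscopy images.

## The problem

Ligand-coupled latex beads (~1 µm) are used to mimic bacterial invasion of
cultured cells; quantifying an experiment means counting beads that appear as
bright spots of only **2–4 px diameter** in the fluorescence channel.  At that
scale touching beads share pixel edges, classical blob detectors need per-
dataset parameter tuning, and manual counting is slow and biased.

`beadspot` implements a learned pipeline around one key idea: **fourfold
bilinear upsampling** makes the centers of touching beads separable, so bead
detection becomes ordinary semantic segmentation of tiny disjoint *seed*
markers.

The pipeline:

1. **Preprocess** — percentile min–max normalization, 4× bilinear upsampling
   (pixel-area aligned), ground-truth centroids rendered as 2×2 px seed
   blocks, optionally enlarged by a cross-shaped (plus) morphological
   dilation.
2. **Detect** — a compact U-Net (depth 3, batch-norm/ReLU blocks, sigmoid
   head) trained with the compound loss
   `L = BCE(p, t) + 1 − (2Σpt + 1)/(Σp + Σt + 1)`
   (pixel-mean binary cross-entropy plus smoothed Dice), with online
   augmentation (flips, 90° rotations, gain, noise, blur).  Several random
   initializations are trained with and without label dilation, and the model
   with the best detection F-score on a held-out split is selected
   automatically.
3. **Post-process** — threshold at 0.5, 8-connected component labeling,
   unweighted centroids, count.
4. **Evaluate** — ground-truth seeds are enlarged to 8×8 regions; predictions
   are scored as *missing* (bead with no predicted seed), *split* (bead with
   several) and *added* (prediction in background, excluding a border margin
   where partially visible beads are never annotated).  From
   TP = beads hit, FP = added + split surplus, FN = missed:
   `Q_P = TP/(TP+FP)`, `Q_R = TP/(TP+FN)`, `Q_F = 2·Q_P·Q_R/(Q_P+Q_R)`,
   plus `Q_split`, `Q_miss`, `Q_add` and total detections as % of beads.

Three classical baselines are included for comparison: scale-normalized
Laplacian-of-Gaussian seeding, circular Hough transform with gradient voting,
and Otsu thresholding with Euclidean-distance-transform maxima.

A synthetic scene generator (Gaussian spots with FWHM = bead diameter,
touching pairs, partially visible border beads, Gaussian/Poisson noise)
makes every stage testable without any external data.

The network layer stack (convolutions, batch norm, pooling, Adam) is
implemented directly over NumPy with explicit backward passes; training the
default models takes a few minutes on one CPU core and is fully
deterministic for a fixed seed.

## Worked example

```bash
# a synthetic dataset: 60 train / 15 val / 25 test images, 32x32 px,
# ~26 beads of 2-4 px diameter per image
beadspot generate --out data --seed 1

# train 2 models with and 2 without label dilation, auto-select on val.
# the generator leaves beads whose extent crosses the border unannotated,
# so scoring ignores background predictions within 8 upsampled px of an edge
beadspot train --dataset data --out run --seed 1 --border-margin 8

# score the selected model and the classical baselines on the test split
for m in otsu log hough; do
  beadspot bench --dataset data --split test --method $m --out run --border-margin 8
done
beadspot bench --dataset data --split test --method detector \
    --model run/model --out run --border-margin 8
```

This prints (training takes a few minutes per model on one CPU core):

```
INFO beadspot: trained 4 models in 931.5s; selected Q_F=0.935 (dilation=False)
INFO beadspot: otsu: Q_F=0.799 detections=75.83% (0.2s, 25 images)
INFO beadspot: log: Q_F=0.805 detections=85.39% (0.3s, 25 images)
INFO beadspot: hough: Q_F=0.585 detections=42.09% (0.2s, 25 images)
INFO beadspot: detector: Q_F=0.933 detections=92.00% (1.4s, 25 images)
```

and writes the seven-column report (`Q_F, Q_P, Q_R, Q_split, Q_miss, Q_add,
detections`) as CSV/JSON per method.  The learned detector both misses and
invents far fewer beads than the tuned classical detectors on the same
images; the Otsu and Hough baselines mostly fail on touching pairs and dim
beads (detections far below 100 %), which is exactly the failure mode the
upsampling + seed-segmentation design addresses.

Library use mirrors the CLI:

```python
import beadspot as bs

image, ann = bs.generate_scene(bs.SceneConfig(rng_seed=7))
bundle = bs.train_model(train_set, val_set, bs.NetConfig(), use_dilation=False)
detections = bs.detect_beads(bundle, image)          # centroids, upsampled frame
report, _ = bs.evaluate_detector(test_set, lambda im: bs.detect_beads(bundle, im))
```

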