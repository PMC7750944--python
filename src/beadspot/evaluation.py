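"""Detection evaluation: missing / split / added accounting with border
correction, and the summary metrics reported for bead counting.

Scheme
------
Ground-truth seeds (2x2 px blocks in the upsampled frame) are enlarged to
square regions; a predicted centroid falling inside a bead's region is
credited to that bead.  Per ground-truth bead the number of credited seeds
gives:

* **missing** -- beads with 0 predicted seeds,
* **split**   -- beads with >= 2 predicted seeds,
* **added**   -- predictions in the background, excluding those within a
  border margin of the image edge (partially visible border beads are not
  annotated, so predictions there cannot be scored fairly).

From these, with TP = beads hit at least once, FN = missing beads and
FP = added predictions + surplus seeds on split beads:

    Q_P = TP / (TP + FP)            precision
    Q_R = TP / (TP + FN)            recall
    Q_F = 2 Q_P Q_R / (Q_P + Q_R)   F-score
    Q_split, Q_miss, Q_add          as % of ground-truth beads
    detections = (TP + surplus + added) / n_gt * 100

Evaluation across a test set is pooled (micro-averaged): match tables are
summed over images before computing one report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .postprocess import DetectionSet


@dataclass
class MatchTable:
    """Per-bead predicted-seed counts plus background-prediction counts."""

    seeds_per_bead: np.ndarray = field(default_factory=lambda: np.empty((0,), dtype=int))
    n_added: int = 0
    n_border_ignored: int = 0

    def __post_init__(self) -> None:
        self.seeds_per_bead = np.asarray(self.seeds_per_bead, dtype=int).reshape(-1)

    @property
    def n_gt(self) -> int:
        return len(self.seeds_per_bead)

    @staticmethod
    def from_error_counts(
        n_gt: int, n_missing: int, n_split: int, n_added: int, seeds_on_split: int = 2
    ) -> "MatchTable":
        """Build a table from aggregate error counts.

        ``n_split`` beads get ``seeds_on_split`` seeds each, ``n_missing``
        get none, the rest exactly one.  Useful for reconstructing published
        summary rows as worked examples.
        """
        if n_missing + n_split > n_gt:
            raise ValueError("missing + split cannot exceed n_gt")
        seeds = np.ones(n_gt, dtype=int)
        seeds[:n_missing] = 0
        seeds[n_missing : n_missing + n_split] = seeds_on_split
        return MatchTable(seeds, n_added=n_added)

    def __add__(self, other: "MatchTable") -> "MatchTable":
        return MatchTable(
            np.concatenate([self.seeds_per_bead, other.seeds_per_bead]),
            self.n_added + other.n_added,
            self.n_border_ignored + other.n_border_ignored,
        )


@dataclass
class EvalReport:
    """The seven summary metrics (rates in %, scores in [0, 1])."""

    Q_F: float
    Q_P: float
    Q_R: float
    Q_split: float
    Q_miss: float
    Q_add: float
    detections: float

    COLUMNS = ["Q_F", "Q_P", "Q_R", "Q_split", "Q_miss", "Q_add", "detections"]

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.COLUMNS}


def enlarge_gt(
    gt_centroids: np.ndarray,
    shape: tuple[int, int],
    enlargement_halfwidth: int = 3,
) -> np.ndarray:
    """Enlarge each ground-truth seed into a labeled square region.

    Each bead ``i`` (label ``i + 1``) claims the square of side
    ``2*halfwidth + 2`` whose center is nearest its (upsampled-frame)
    centroid -- i.e. its 2x2 seed grown by ``halfwidth`` on every side;
    the default gives an 8x8 region for 4x-upsampled 2 px beads.  Pixels
    claimed by several beads go to the nearest centroid (Euclidean, ties to
    the lower bead index).  Regions are clipped at the image edge.
    """
    h, w = shape
    labels = np.zeros((h, w), dtype=np.int32)
    cents = np.asarray(gt_centroids, dtype=float).reshape(-1, 2)
    side = 2 * enlargement_halfwidth + 2
    for i, (r, c) in enumerate(cents):
        r0, c0 = preprocess._block_start(np.array([r, c]), side)
        rs = slice(max(r0, 0), min(r0 + side, h))
        cs = slice(max(c0, 0), min(c0 + side, w))
        block = labels[rs, cs]
        free = block == 0
        if np.all(free):
            block[:] = i + 1
            continue
        rr, cc = np.mgrid[rs, cs]
        d_new = (rr - r) ** 2 + (cc - c) ** 2
        prev = block.copy()
        occupied = ~free
        pr = cents[prev[occupied] - 1]
        d_old = (rr[occupied] - pr[:, 0]) ** 2 + (cc[occupied] - pr[:, 1]) ** 2
        take = np.zeros_like(block, dtype=bool)
        take[free] = True
        # strict <: on exact ties the earlier (lower-index) bead keeps the pixel
        take[occupied] = d_new[occupied] < d_old
        block[take] = i + 1
    return labels


def match_detections(
    gt_regions: np.ndarray,
    predictions: DetectionSet | np.ndarray,
    border_margin: int = 4,
) -> MatchTable:
    """Assign each predicted centroid to a ground-truth region or background.

    Centroids are rounded to the nearest pixel.  Background predictions
    within ``border_margin`` px of any image edge are ignored (border
    correction); the rest count as added.  Predictions falling outside the
    raster are tallied as border-ignored.
    """
    gt_regions = np.asarray(gt_regions)
    h, w = gt_regions.shape
    n_gt = int(gt_regions.max())
    seeds = np.zeros(n_gt, dtype=int)
    added = 0
    border = 0
    cents = predictions.centroids if isinstance(predictions, DetectionSet) else predictions
    cents = np.asarray(cents, dtype=float).reshape(-1, 2)
    for r, c in cents:
        pr, pc = int(np.floor(r + 0.5)), int(np.floor(c + 0.5))
        if not (0 <= pr < h and 0 <= pc < w):
            border += 1
            continue
        lab = gt_regions[pr, pc]
        if lab > 0:
            seeds[lab - 1] += 1
        elif pr < border_margin or pr >= h - border_margin or pc < border_margin or pc >= w - border_margin:
            border += 1
        else:
            added += 1
    return MatchTable(seeds, n_added=added, n_border_ignored=border)


def compute_metrics(table: MatchTable) -> EvalReport:
    """Summary metrics from a (possibly pooled) match table."""
    n_gt = table.n_gt
    if n_gt == 0:
        raise ValueError("metrics undefined for zero ground-truth beads")
    seeds = table.seeds_per_bead
    miss = int(np.sum(seeds == 0))
    split = int(np.sum(seeds >= 2))
    extra = int(np.sum(np.maximum(seeds - 1, 0)))
    tp = n_gt - miss
    fp = table.n_added + extra
    fn = miss
    q_p = tp / (tp + fp) if tp + fp > 0 else 0.0
    q_r = tp / (tp + fn)
    q_f = 2 * q_p * q_r / (q_p + q_r) if tp > 0 else 0.0
    return EvalReport(
        Q_F=q_f,
        Q_P=q_p,
        Q_R=q_r,
        Q_split=100.0 * split / n_gt,
        Q_miss=100.0 * miss / n_gt,
        Q_add=100.0 * table.n_added / n_gt,
        detections=100.0 * (tp + extra + table.n_added) / n_gt,
    )


def evaluate_image(
    gt_centroids_up: np.ndarray,
    predictions: DetectionSet | np.ndarray,
    shape: tuple[int, int],
    enlargement_halfwidth: int = 3,
    border_margin: int = 4,
) -> MatchTable:
    """Match predictions against ground truth for one upsampled image."""
    regions = enlarge_gt(gt_centroids_up, shape, enlargement_halfwidth)
    return match_detections(regions, predictions, border_margin)


def evaluate_detector(
    samples,
    detector,
    factor: int = 4,
    enlargement_halfwidth: int = 3,
    border_margin: int = 4,
) -> tuple[EvalReport, list[MatchTable]]:
    """Run ``detector`` over a test set and compute one pooled report.

    ``samples`` is an iterable of ``(image, gt_centroids_original)`` pairs at
    original resolution; ``detector`` is a callable mapping an original-
    resolution image to a DetectionSet in the upsampled frame.  Counts are
    pooled (summed) across images before the metrics are computed, so the
    report reflects the concatenated test set, not a mean of per-image
    scores.  Per-image tables are returned alongside.
    """
    tables: list[MatchTable] = []
    for image, gt in samples:
        gt = np.asarray(gt, dtype=float).reshape(-1, 2)
        dets = detector(image)
        shape = (image.shape[0] * factor, image.shape[1] * factor)
        gt_up = preprocess.map_centroid_up(gt, factor)
        tables.append(
            evaluate_image(gt_up, dets, shape, enlargement_halfwidth, border_margin)
        )
    if not tables:
        raise ValueError("no usable images with ground truth")
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t
    return compute_metrics(pooled), tables
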