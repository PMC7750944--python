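"""Classical bead detectors used as comparison baselines.

Three detectors that a practitioner would reach for before training a
network, all operating on a normalized grayscale image and returning point
detections in the coordinates of that image (callers typically run them on
the upsampled image):

* :func:`detect_log` -- scale-normalized Laplacian-of-Gaussian blob
  detection, the seed-detection stage of LoG-based spot pipelines.
* :func:`detect_hough` -- classic circular Hough transform with gradient-
  direction voting, in the spirit of MATLAB's ``imfindcircles``.
* :func:`detect_otsu_edt` -- global Otsu threshold followed by Euclidean-
  distance-transform maxima, the simplest watershed-style seeding.

All three need the bead diameter range as a parameter -- exactly the kind of
tuning burden the learned detector removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .postprocess import DetectionSet, label_components


@dataclass
class BaselineParams:
    """Shared parameters; diameters in px at the resolution the detector
    runs on.  ``min_distance`` defaults to the minimum diameter."""

    diameter_range: tuple[float, float] = (8.0, 16.0)
    log_rel_threshold: float = 0.1
    hough_sensitivity: float = 0.5
    min_distance: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.log_rel_threshold <= 1.0):
            raise ValueError("log_rel_threshold must be in (0, 1]")
        if not (0.0 < self.hough_sensitivity <= 1.0):
            raise ValueError("hough_sensitivity must be in (0, 1]")
        if self.min_distance is None:
            self.min_distance = self.diameter_range[0]
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")


def local_maxima(response: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Strict 8-neighborhood local maxima, one representative per plateau.

    A pixel qualifies if no 8-neighbor exceeds it; plateaus (connected
    regions of equal value that dominate their surroundings) contribute
    their lexicographically smallest (row, col) pixel.  Returns (n, 2) int
    coordinates.
    """
    response = np.asarray(response, dtype=float)
    peaks = morphology.local_maxima(response, connectivity=2, allow_borders=True)
    if mask is not None:
        peaks &= np.asarray(mask) > 0
    if not peaks.any():
        return np.empty((0, 2), dtype=int)
    labeled, n = ndimage.label(peaks, structure=np.ones((3, 3), bool))
    coords = [
        min(map(tuple, np.argwhere(labeled == lab))) for lab in range(1, n + 1)
    ]
    return np.array(sorted(coords), dtype=int)


def nms_points(
    points: np.ndarray, scores: np.ndarray, min_distance: float
) -> np.ndarray:
    """Greedy non-maximum suppression, strongest first.

    Ties in score are broken by smaller (row, col) so the result is
    deterministic.  Returns the surviving points ordered by decreasing
    score.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    order = np.lexsort((points[:, 1], points[:, 0], -scores))
    kept: list[int] = []
    for i in order:
        p = points[i]
        if all(np.hypot(*(p - points[j])) >= min_distance for j in kept):
            kept.append(i)
    return points[kept]


def detect_log(image: np.ndarray, params: BaselineParams) -> DetectionSet:
    """Scale-normalized LoG blob detection for bright spots.

    Responses ``-sigma^2 * LoG(I, sigma)`` are computed at three scales with
    ``sigma = d / (2*sqrt(2))`` spanning the diameter range, maximized over
    scale, and thresholded at ``log_rel_threshold`` times the global maximum
    response; surviving local maxima are greedily suppressed to
    ``min_distance`` separation.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        return DetectionSet(source="log")
    d_lo, d_hi = params.diameter_range
    sigmas = np.linspace(d_lo, d_hi, 3) / (2.0 * np.sqrt(2.0))
    resp = np.max(
        [-(s**2) * ndimage.gaussian_laplace(image, s) for s in sigmas], axis=0
    )
    peaks = local_maxima(resp)
    if len(peaks) == 0:
        return DetectionSet(source="log")
    vals = resp[peaks[:, 0], peaks[:, 1]]
    keep = vals > params.log_rel_threshold * resp.max()
    peaks, vals = peaks[keep], vals[keep]
    if len(peaks) == 0:
        return DetectionSet(source="log")
    pts = nms_points(peaks, vals, params.min_distance)
    return DetectionSet(pts, np.ones(len(pts), dtype=int), source="log")


def detect_hough(image: np.ndarray, params: BaselineParams) -> DetectionSet:
    """Circular Hough transform with gradient-direction voting.

    Edges are gradient-magnitude pixels above the Otsu threshold of the
    magnitude map; each edge pixel casts one vote per integer radius in
    ``diameter_range / 2`` at the point ``radius`` px along its gradient
    direction (towards the bright interior).  Accumulators are lightly
    smoothed, maximized over radius, and peaks above ``hough_sensitivity``
    times the maximum are suppressed to ``min_distance``.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        return DetectionSet(source="hough")
    r_lo = int(round(params.diameter_range[0] / 2.0))
    r_hi = int(round(params.diameter_range[1] / 2.0))
    radii = [r for r in range(max(r_lo, 1), r_hi + 1)]
    if not radii:
        raise ValueError("radius range empty after rounding")
    gr = ndimage.sobel(image, axis=0)
    gc = ndimage.sobel(image, axis=1)
    mag = np.hypot(gr, gc)
    if mag.max() <= 0:
        return DetectionSet(source="hough")
    edges = mag > otsu_threshold(mag)
    er, ec = np.nonzero(edges)
    if er.size == 0:
        return DetectionSet(source="hough")
    ur = gr[er, ec] / mag[er, ec]
    uc = gc[er, ec] / mag[er, ec]
    h, w = image.shape
    acc = np.zeros((len(radii), h, w))
    for k, radius in enumerate(radii):
        vr = np.rint(er + radius * ur).astype(int)
        vc = np.rint(ec + radius * uc).astype(int)
        ok = (vr >= 0) & (vr < h) & (vc >= 0) & (vc < w)
        np.add.at(acc[k], (vr[ok], vc[ok]), mag[er, ec][ok])
        acc[k] = ndimage.gaussian_filter(acc[k], 1.0)
    resp = acc.max(axis=0)
    peaks = local_maxima(resp)
    if len(peaks) == 0:
        return DetectionSet(source="hough")
    vals = resp[peaks[:, 0], peaks[:, 1]]
    keep = vals > params.hough_sensitivity * resp.max()
    peaks, vals = peaks[keep], vals[keep]
    if len(peaks) == 0:
        return DetectionSet(source="hough")
    pts = nms_points(peaks, vals, params.min_distance)
    return DetectionSet(pts, np.ones(len(pts), dtype=int), source="hough")


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's global threshold: the histogram bin maximizing between-class
    variance over ``nbins`` equal-width bins; returns the bin center.

    Ties go to the lowest qualifying bin.
    """
    values = np.asarray(image, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return float(lo)
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist.astype(float) / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -np.inf
    return float(centers[int(np.argmax(var_between))])


def detect_otsu_edt(
    image: np.ndarray, params: BaselineParams | None = None
) -> DetectionSet:
    """Otsu threshold + Euclidean-distance-transform maxima.

    The foreground mask is ``image > otsu``; detections are distance-map
    local maxima within the foreground at ``min_distance`` separation.
    Merged beads survive as separate detections only while each keeps its
    own distance maximum -- the characteristic under-segmentation failure of
    this approach.  Foreground components left without a detection
    contribute their centroid.
    """
    params = params or BaselineParams()
    image = np.asarray(image, dtype=float)
    fg = image > otsu_threshold(image)
    if not fg.any():
        return DetectionSet(source="otsu")
    edt = ndimage.distance_transform_edt(fg)
    peaks = local_maxima(edt, mask=fg)
    if len(peaks):
        vals = edt[peaks[:, 0], peaks[:, 1]]
        pts = nms_points(peaks, vals, params.min_distance)
    else:
        pts = np.empty((0, 2))
    labeled = label_components(fg)
    covered = set()
    for r, c in pts.astype(int):
        covered.add(labeled[r, c])
    extras = []
    for lab in range(1, labeled.max() + 1):
        if lab not in covered:
            pix = np.argwhere(labeled == lab)
            extras.append(pix.mean(axis=0))
    if extras:
        pts = np.vstack([pts, np.asarray(extras)]) if len(pts) else np.asarray(extras)
    return DetectionSet(pts, np.ones(len(pts), dtype=int), source="otsu")
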