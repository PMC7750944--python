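"""Post-processing: probability map -> thresholded seeds -> centroids -> count."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: 8-connectivity structuring element for component labeling.
EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionSet:
    """Detected bead centers at the resolution of the raster they came from.

    One centroid per connected component; ``sizes`` holds the component
    pixel counts (or 1 for point detections from the classical detectors).
    """

    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    sizes: np.ndarray = field(default_factory=lambda: np.empty((0,), dtype=int))
    source: str = "detector"

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.sizes = np.asarray(self.sizes, dtype=int).reshape(-1)

    def __len__(self) -> int:
        return len(self.centroids)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Global threshold, strict ``>`` (a pixel exactly at threshold is off)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (np.asarray(prob) > threshold).astype(np.uint8)


def label_components(binary: np.ndarray) -> np.ndarray:
    """8-connected component labeling: labels 1..K, background 0."""
    labeled, _ = ndimage.label(np.asarray(binary) > 0, structure=EIGHT_CONN)
    return labeled


def extract_centroids(
    labeled: np.ndarray, min_size: int = 1, source: str = "detector"
) -> DetectionSet:
    """Unweighted mean pixel coordinate of each component.

    Components smaller than ``min_size`` pixels are discarded (default 1,
    i.e. no filtering).
    """
    labeled = np.asarray(labeled)
    n = int(labeled.max())
    if n == 0:
        return DetectionSet(source=source)
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, idx).astype(int)
    cents = np.asarray(ndimage.center_of_mass(np.ones_like(labeled), labeled, idx))
    keep = sizes >= min_size
    return DetectionSet(cents[keep], sizes[keep], source=source)


def count_beads(detections: DetectionSet) -> int:
    """Number of detected beads."""
    return len(detections)


def detections_from_probability(
    prob: np.ndarray, threshold: float = 0.5, min_size: int = 1, source: str = "detector"
) -> DetectionSet:
    """Convenience chain: binarize -> label -> centroids."""
    return extract_centroids(label_components(binarize(prob, threshold)), min_size, source)
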