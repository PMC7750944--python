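"""Preprocessing: intensity normalization, bilinear upsampling, seed labels.

The key idea of the pipeline is that beads of 2-4 px diameter cannot be
separated at native resolution once they touch, but after integer-factor
bilinear upsampling their centers no longer share an edge and the problem
becomes ordinary semantic segmentation of small, disjoint "seed" blocks.

Coordinate convention (pixel-area alignment)
--------------------------------------------
Original pixel ``c`` maps to the block ``[factor*c, factor*c + factor - 1]``
of the upsampled grid, whose center sits at ``factor*c + (factor - 1)/2``.
Equivalently, upsampled pixel ``y`` samples the original image at
``(y - (factor - 1)/2) / factor``, clamped to the image for the border
half-pixels.  This is the convention under which a 2x2 seed block lands
symmetrically on an integer original centroid after 4x upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class UpsampleSpec:
    """Upsampling configuration; interpolation is always bilinear."""

    factor: int = 4

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("upsampling factor must be >= 1")


@dataclass
class SeedMask:
    """Binary seed-label raster at upsampled resolution."""

    data: np.ndarray
    seed_size: int = 2
    dilated: bool = False
    n_skipped: int = 0  # centroids outside the image, dropped with a warning count

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def factor_for_diameter_range(diameter_range: tuple[float, float]) -> int:
    """Map a bead diameter range to an upsampling factor.

    Small beads need more upsampling before their seeds separate; we use
    factor = ceil(8 / min_diameter), which gives the default factor 4 for
    2 px beads.
    """
    lo = diameter_range[0]
    if lo <= 0:
        raise ValueError("minimum diameter must be positive")
    return max(1, int(np.ceil(8.0 / lo)))


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Robust min-max normalization to [0, 1] using the 1st/99th percentiles.

    Values outside the percentile window are clipped; a constant image maps
    to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(image, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def upsample_bilinear(image: np.ndarray, spec: UpsampleSpec | int = UpsampleSpec()) -> np.ndarray:
    """Bilinearly upsample by an integer factor under pixel-area alignment.

    Output shape is exactly ``(factor*H, factor*W)``; border half-pixels
    replicate the edge value (clamped sampling), so the intensity range is
    preserved.
    """
    if isinstance(spec, int):
        spec = UpsampleSpec(spec)
    f = spec.factor
    image = np.asarray(image, dtype=float)
    if f == 1:
        return image.copy()
    h, w = image.shape
    rows = (np.arange(f * h) - (f - 1) / 2.0) / f
    cols = (np.arange(f * w) - (f - 1) / 2.0) / f
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(image, grid, order=1, mode="nearest")


def map_centroid_up(centroid, factor: int):
    """Map original-resolution (row, col) to the upsampled frame.

    ``(r, c) -> (factor*r + (factor-1)/2, factor*c + (factor-1)/2)`` -- the
    center of the block of upsampled pixels covering the original pixel.
    Accepts a single pair or an (n, 2) array.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(centroid, dtype=float)
    return arr * factor + (factor - 1) / 2.0


def map_centroid_down(centroid, factor: int):
    """Inverse of :func:`map_centroid_up`."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(centroid, dtype=float)
    return (arr - (factor - 1) / 2.0) / factor


def _block_start(center: np.ndarray, size: int) -> np.ndarray:
    """Start index of the ``size``-long block whose center is nearest
    ``center``; exact ties resolved toward the smaller index."""
    return np.ceil(center - (size - 1) / 2.0 - 0.5).astype(int)


def render_seed_mask(
    centroids: np.ndarray,
    shape: tuple[int, int],
    seed_size: int = 2,
) -> SeedMask:
    """Paint one ``seed_size`` x ``seed_size`` block per centroid.

    ``centroids`` are (row, col) in the *upsampled* frame.  Each block is
    the one whose center is nearest the centroid (ties toward smaller
    indices) and is clipped at the image edge.  Centroids outside the image
    are skipped and counted in ``n_skipped``.

    For the default 4x upsampling of an integer original centroid (r, c)
    this sets exactly rows {4r+1, 4r+2} x cols {4c+1, 4c+2}.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    skipped = 0
    cents = np.asarray(centroids, dtype=float).reshape(-1, 2)
    for r, c in cents:
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            skipped += 1
            continue
        r0, c0 = _block_start(np.array([r, c]), seed_size)
        r1, c1 = r0 + seed_size, c0 + seed_size
        mask[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] = 1
    return SeedMask(mask, seed_size=seed_size, dilated=False, n_skipped=skipped)


#: 3x3 plus-shaped (cross) structuring element used to dilate seed labels.
CROSS_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def dilate_seeds_cross(mask: SeedMask | np.ndarray) -> SeedMask:
    """Morphological dilation of the seed labels with the 3x3 cross.

    Enlarging the training targets makes the seed detection more forgiving,
    at the cost that seeds of beads less than ~1 original px apart can merge
    into one component (which then counts as a single detection).
    """
    if isinstance(mask, SeedMask):
        data, seed_size = mask.data, mask.seed_size
    else:
        data, seed_size = np.asarray(mask), 2
    out = ndimage.binary_dilation(data > 0, structure=CROSS_STRUCTURE).astype(np.uint8)
    return SeedMask(out, seed_size=seed_size, dilated=True)


def prepare_sample(
    image: np.ndarray,
    centroids_original: np.ndarray,
    factor: int = 4,
    seed_size: int = 2,
    use_dilation: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Full preprocessing of one training pair.

    Normalizes and upsamples the image, maps the ground-truth centroids into
    the upsampled frame and renders the (optionally cross-dilated) seed
    label mask.  Returns ``(image_up, mask)`` as float/uint8 arrays.
    """
    img = upsample_bilinear(normalize_intensity(image), UpsampleSpec(factor))
    cents_up = map_centroid_up(np.asarray(centroids_original, float).reshape(-1, 2), factor)
    mask = render_seed_mask(cents_up, img.shape, seed_size=seed_size)
    if use_dilation:
        mask = dilate_seeds_cross(mask)
    return img, mask.data
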