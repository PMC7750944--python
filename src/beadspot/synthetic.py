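"""Synthetic low-resolution bead image generator.

Emulates the kind of data the detector is built for: single-channel
fluorescence images a few tens of pixels across, containing sub-resolution
latex beads that appear as bright spots of roughly 2-4 px diameter, some of
them touching, some only partially inside the field of view.  Every scene
comes with exact ground-truth centroids, so the whole pipeline (upsampling,
seed rendering, training, detection, evaluation) is testable without any
external data.

Spot model
----------
Each bead is rendered as an isotropic 2D Gaussian whose full width at half
maximum equals the nominal bead diameter (sigma = diameter / 2.3548) and
whose peak intensity is the bead amplitude.  This is the standard
approximation of a diffraction-limited point emitter.  Images are float in
[0, 1]: background level, plus the sum of bead profiles, plus optional
Poisson shot noise and Gaussian read noise, clipped back into range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bsio

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian profile
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: Retries allowed per bead before placement gives up.
_PLACEMENT_RETRIES = 200


class PlacementError(RuntimeError):
    """Raised when a scene cannot accommodate the requested bead count."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic bead scene.

    Defaults describe a 32 x 32 px field with a bead density comparable to
    real low-resolution bead assays (~26 beads per 32 x 32 px tile), bead
    diameters of 2-4 px, a fifth of the beads touching a neighbour, and
    moderate Gaussian read noise.  ``poisson_scale`` > 0 additionally applies
    shot noise with that photon-count scaling; 0 disables it.
    """

    width: int = 32
    height: int = 32
    n_beads: int = 26
    diameter_range: tuple[float, float] = (2.0, 4.0)
    touching_fraction: float = 0.2
    amplitude_range: tuple[float, float] = (0.4, 0.9)
    background_level: float = 0.1
    noise_sigma: float = 0.05
    poisson_scale: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must be in [0, 1]")
        lo, hi = self.diameter_range
        if not (0.0 < lo <= hi):
            raise ValueError("diameter_range must satisfy 0 < min <= max")
        if hi >= min(self.width, self.height) / 2:
            raise ValueError("diameter_range too large for the image size")


@dataclass
class SceneAnnotation:
    """Ground truth for one scene: per-bead centroid, diameter, visibility.

    Centroids are 0-based (row, col) at original resolution, pixel centers on
    integer coordinates.  ``fully_visible`` marks beads whose full nominal
    extent (diameter/2 around the centre) lies inside the image; only those
    are meant to be scored, mirroring annotation practice where partially
    visible border beads are left unannotated.
    """

    centroids: list[tuple[float, float]] = field(default_factory=list)
    diameters: list[float] = field(default_factory=list)
    fully_visible: list[bool] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)  # not exported to CSV

    def __len__(self) -> int:
        return len(self.centroids)

    def visible_centroids(self) -> np.ndarray:
        """(n, 2) array of the fully visible centroids."""
        sel = [c for c, v in zip(self.centroids, self.fully_visible) if v]
        return np.asarray(sel, dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bead_id": np.arange(len(self.centroids)),
                "row": [r for r, _ in self.centroids],
                "col": [c for _, c in self.centroids],
                "diameter": self.diameters,
                "fully_visible": [int(v) for v in self.fully_visible],
            }
        )


def render_bead(
    centroid: tuple[float, float],
    diameter: float,
    amplitude: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Render one bead as a Gaussian spot with FWHM = ``diameter``.

    The profile is evaluated at pixel centers (integer coordinates) and has
    peak value ``amplitude`` at the centroid.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    sigma = diameter / FWHM_TO_SIGMA
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    r0, c0 = centroid
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _place_centroids(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Random sequential placement with a minimum-separation rule.

    Isolated beads keep >= 3 px between centers; a ``touching_fraction``
    share of beads is instead dropped 1-2 px from an existing bead so that
    the spots overlap, which is the regime upsampling is meant to resolve.
    """
    h, w = config.height, config.width
    n = config.n_beads
    placed: list[tuple[float, float]] = []
    n_touching = int(round(config.touching_fraction * n)) if n > 1 else 0
    min_sep = 3.0

    for i in range(n):
        attach = i >= n - n_touching and placed
        for _ in range(_PLACEMENT_RETRIES):
            if attach:
                anchor = placed[rng.integers(len(placed))]
                dist = rng.uniform(1.0, 2.0)
                angle = rng.uniform(0.0, 2.0 * np.pi)
                cand = (
                    anchor[0] + dist * np.sin(angle),
                    anchor[1] + dist * np.cos(angle),
                )
                if not (0.5 <= cand[0] <= h - 1.5 and 0.5 <= cand[1] <= w - 1.5):
                    continue
                others = [p for p in placed if p is not anchor]
                ok = all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in others)
            else:
                cand = (rng.uniform(0.5, h - 1.5), rng.uniform(0.5, w - 1.5))
                ok = all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in placed)
            if ok:
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place bead {i + 1}/{n} within {_PLACEMENT_RETRIES} retries"
            )
    return np.asarray(placed, dtype=float).reshape(-1, 2)


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, SceneAnnotation]:
    """Generate one scene: float image in [0, 1] plus its annotation.

    Deterministic for a fixed ``config.rng_seed``.  With ``noise_sigma`` and
    ``poisson_scale`` both 0 the image equals background + analytic bead sum
    exactly (clipped to [0, 1]).
    """
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.height, config.width
    centroids = _place_centroids(config, rng)

    ann = SceneAnnotation()
    clean = np.full((h, w), config.background_level, dtype=float)
    for r0, c0 in centroids:
        d = rng.uniform(*config.diameter_range)
        a = rng.uniform(*config.amplitude_range)
        clean += render_bead((r0, c0), d, a, (h, w))
        half = d / 2.0
        visible = (
            r0 - half >= 0 and r0 + half <= h - 1 and c0 - half >= 0 and c0 + half <= w - 1
        )
        ann.centroids.append((float(r0), float(c0)))
        ann.diameters.append(float(d))
        ann.fully_visible.append(bool(visible))
        ann.amplitudes.append(float(a))

    image = clean
    if config.poisson_scale > 0:
        image = rng.poisson(np.clip(image, 0, None) * config.poisson_scale) / config.poisson_scale
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=(h, w))
    return np.clip(image, 0.0, 1.0), ann


def generate_dataset(
    n_train: int,
    n_val: int,
    n_test: int,
    config: SceneConfig | None = None,
    out_dir: str | Path = ".",
    master_seed: int | None = None,
) -> dict:
    """Write a train/val/test dataset of TIFF images and centroid CSVs.

    Default split sizes used throughout the project are 60/15/25.  Per-image
    seeds are derived deterministically from the master seed (default: the
    config's ``rng_seed``), so regeneration is byte-identical.  Returns the
    manifest, which is also written to ``out_dir/manifest.json``.
    """
    config = config or SceneConfig()
    if master_seed is None:
        master_seed = config.rng_seed
    out = Path(out_dir)
    manifest: dict = {"master_seed": int(master_seed), "splits": {}}
    splits = [("train", n_train), ("val", n_val), ("test", n_test)]
    for split_idx, (split, count) in enumerate(splits):
        split_dir = out / split
        split_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for img_idx in range(count):
            seq = np.random.SeedSequence(master_seed, spawn_key=(split_idx, img_idx))
            seed = int(seq.generate_state(1)[0] % (2**31))
            cfg = SceneConfig(**{**config.__dict__, "rng_seed": seed})
            image, ann = generate_scene(cfg)
            stem = f"image_{img_idx:03d}"
            bsio.write_image(image.astype(np.float32), split_dir / f"{stem}.tif")
            bsio.write_centroid_table(ann.to_frame(), split_dir / f"{stem}.csv")
            entries.append({"image": f"{split}/{stem}.tif", "centroids": f"{split}/{stem}.csv", "seed": seed})
        manifest["splits"][split] = entries
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_split_samples(
    n_train: int,
    n_val: int,
    n_test: int,
    config: SceneConfig | None = None,
    master_seed: int = 0,
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """In-memory version of :func:`generate_dataset`.

    Returns ``{"train": [...], "val": [...], "test": [...]}`` where each
    entry is an ``(image, visible_centroids)`` pair, with per-image seeds
    derived exactly as :func:`generate_dataset` derives them.
    """
    config = config or SceneConfig()
    out: dict[str, list] = {}
    for split_idx, (split, count) in enumerate(
        [("train", n_train), ("val", n_val), ("test", n_test)]
    ):
        samples = []
        for img_idx in range(count):
            seq = np.random.SeedSequence(master_seed, spawn_key=(split_idx, img_idx))
            seed = int(seq.generate_state(1)[0] % (2**31))
            cfg = SceneConfig(**{**config.__dict__, "rng_seed": seed})
            image, ann = generate_scene(cfg)
            samples.append((image, ann.visible_centroids()))
        out[split] = samples
    return out


def load_dataset_split(dataset_dir: str | Path, split: str) -> list[tuple[np.ndarray, pd.DataFrame]]:
    """Load (image, centroid table) pairs for one split via the manifest."""
    root = Path(dataset_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    out = []
    for entry in manifest["splits"][split]:
        image = bsio.read_image(root / entry["image"])
        table = bsio.read_centroid_table(root / entry["centroids"])
        out.append((image, table))
    return out
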