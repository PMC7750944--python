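"""The learned seed detector.

A compact U-Net is trained to paint the 2x2 px seed of every bead in the
bilinearly upsampled image, optimizing the sum of binary cross-entropy and
Dice loss.  Because touching beads keep a 2 px gap between their seeds after
4x upsampling, thresholding the prediction at 0.5 and labeling connected
components yields one component per bead.

Seed labels can optionally be enlarged with a cross-shaped dilation before
training; this tends to reduce missed beads but can merge the labels of very
close pairs.  Since neither variant dominates, a small model zoo is trained
-- several random initializations with and without dilation -- and the best
model by detection F-score on a held-out split is selected automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import evaluation, preprocess
from .nn import F32, Adam, UNet
from .postprocess import DetectionSet, detections_from_probability

EPS = 1e-7
DICE_SMOOTH = 1.0


@dataclass
class NetConfig:
    """Detector hyperparameters.

    ``input_size`` is the training crop size at *upsampled* resolution and
    must be divisible by ``2**depth``.
    """

    depth: int = 3
    base_channels: int = 32
    input_size: int = 128
    batch_size: int = 4
    max_epochs: int = 20
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.depth, self.base_channels, self.input_size, self.batch_size, self.max_epochs) < 1:
            raise ValueError("all NetConfig counts must be positive")
        if self.input_size % 2**self.depth:
            raise ValueError("input_size must be divisible by 2**depth")


@dataclass
class ModelBundle:
    """A trained model with its configuration and training record."""

    model: UNet
    config: NetConfig
    dilation_used: bool
    history: list[dict] = field(default_factory=list)
    rng_seed: int = 0
    selection_score: float | None = None


def build_detector(config: NetConfig) -> UNet:
    """Instantiate the U-Net for a configuration (weights seeded)."""
    return UNet(config.depth, config.base_channels, rng_seed=config.rng_seed)


# ---------------------------------------------------------------- loss ----


def bce_dice_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Binary cross-entropy plus Dice loss.

    ``pred`` holds probabilities (clamped to [1e-7, 1 - 1e-7]); ``target``
    is binary.  The BCE term is the pixel mean; the Dice term is
    ``1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s)`` with smoothing s = 1.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, EPS, 1.0 - EPS)
    bce = float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    inter = float(np.sum(p * target))
    dice = 1.0 - (2.0 * inter + DICE_SMOOTH) / (float(p.sum() + target.sum()) + DICE_SMOOTH)
    return bce + dice


def _bce_dice_from_logits(logits: np.ndarray, target: np.ndarray):
    """Loss and its gradient w.r.t. the logits (stable, for training)."""
    z = logits.astype(np.float64)
    t = target.astype(np.float64)
    n = z.size
    p = 1.0 / (1.0 + np.exp(-z))
    # BCE via softplus for stability
    bce = float(np.mean(np.logaddexp(0.0, z) - t * z))
    denom = p.sum() + t.sum() + DICE_SMOOTH
    numer = 2.0 * (p * t).sum() + DICE_SMOOTH
    dice = 1.0 - numer / denom
    dp = -(2.0 * t * denom - numer) / denom**2
    dz = (p - t) / n + dp * p * (1.0 - p)
    return bce + dice, dz.astype(F32)


# -------------------------------------------------------- augmentation ----


@dataclass
class AugmentConfig:
    """Online augmentation probabilities and ranges.

    Geometric operations (flips, 90-degree rotations) are applied to image
    and mask alike; photometric operations (gain, additive Gaussian noise,
    Gaussian blur) touch only the image, so masks stay binary.  Blur is off
    by default: blurring at the scale of the inter-seed gap erases the very
    intensity dip that separates touching beads, degrading the detector on
    close pairs.  It remains available for adapting to out-of-focus data.
    """

    p_flip: float = 0.5
    p_rot90: float = 0.5
    p_gain: float = 0.5
    gain_range: tuple[float, float] = (0.8, 1.2)
    p_noise: float = 0.5
    noise_sigma_max: float = 0.05
    p_blur: float = 0.0
    blur_sigma_max: float = 1.0

    @staticmethod
    def none() -> "AugmentConfig":
        """A configuration under which augment_pair is the identity."""
        return AugmentConfig(p_flip=0, p_rot90=0, p_gain=0, p_noise=0, p_blur=0)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    config: AugmentConfig = AugmentConfig(),
):
    """Randomly augment an (image, mask) training pair; deterministic under
    a fixed ``rng`` state."""
    img = np.asarray(image, dtype=float).copy()
    msk = np.asarray(mask).copy()
    if rng.random() < config.p_flip:
        img, msk = img[::-1], msk[::-1]
    if rng.random() < config.p_flip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < config.p_rot90:
        k = int(rng.integers(1, 4))
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    if rng.random() < config.p_gain:
        img = img * rng.uniform(*config.gain_range)
    if rng.random() < config.p_noise:
        img = img + rng.normal(0.0, rng.uniform(0.0, config.noise_sigma_max), img.shape)
    if rng.random() < config.p_blur:
        sigma = rng.uniform(0.0, config.blur_sigma_max)
        if sigma > 0.05:
            img = ndimage.gaussian_filter(img, sigma)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# ------------------------------------------------------------- training ----


def _pad_to_multiple(image: np.ndarray, multiple: int):
    h, w = image.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    return image, (h, w)


def _random_crop(img, msk, size, rng):
    h, w = img.shape
    if h <= size and w <= size:
        return img, msk
    r0 = int(rng.integers(0, max(h - size, 0) + 1))
    c0 = int(rng.integers(0, max(w - size, 0) + 1))
    return img[r0 : r0 + size, c0 : c0 + size], msk[r0 : r0 + size, c0 : c0 + size]


def _epoch_loss(model: UNet, samples, depth: int) -> float:
    """Mean loss over preprocessed (image, mask) pairs in eval mode."""
    total = 0.0
    for img, msk in samples:
        x, orig = _pad_to_multiple(img, 2**depth)
        logits = model.forward(x[None, None], train=False)[0, 0]
        logits = logits[: orig[0], : orig[1]]
        loss, _ = _bce_dice_from_logits(logits, msk)
        total += loss
    return total / len(samples)


def train_model(
    train_set,
    val_set,
    config: NetConfig,
    use_dilation: bool = False,
    factor: int = 4,
    seed_size: int = 2,
    augment: AugmentConfig | None = None,
    crops_per_image: int = 1,
) -> ModelBundle:
    """Train one seed detector.

    ``train_set`` / ``val_set`` are lists of ``(image, centroids)`` pairs at
    original resolution; preprocessing (normalization, upsampling, seed
    rendering, optional cross dilation of the labels) happens here, so the
    dilation flag only ever changes the label masks.  Optimization is Adam
    on BCE+Dice with online augmentation; the epoch checkpoint with the best
    validation loss is kept.  Fully deterministic for a fixed
    ``config.rng_seed``.

    When ``config.input_size`` is smaller than the upsampled images, each
    image contributes ``crops_per_image`` random crops per epoch, which
    multiplies the number of optimizer steps at constant cost per epoch.
    """
    if not train_set:
        raise ValueError("empty training set")
    augment = augment if augment is not None else AugmentConfig()
    prep = lambda s: [
        preprocess.prepare_sample(img, cents, factor, seed_size, use_dilation)
        for img, cents in s
    ]
    train_pairs = prep(train_set)
    val_pairs = prep(val_set) if val_set else []

    rng = np.random.default_rng(config.rng_seed)
    model = build_detector(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_state = model.state()
    for epoch in range(config.max_epochs):
        # cosine decay of the learning rate over the training run
        opt.lr = config.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * epoch / config.max_epochs)
        )
        order = rng.permutation(np.repeat(np.arange(len(train_pairs)), crops_per_image))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = []
            for idx in order[start : start + config.batch_size]:
                img, msk = train_pairs[idx]
                img, msk = augment_pair(img, msk, rng, augment)
                img, msk = _random_crop(img, msk, config.input_size, rng)
                img, _ = _pad_to_multiple(img, 2**config.depth)
                msk, _ = _pad_to_multiple(msk.astype(float), 2**config.depth)
                batch.append((img, msk))
            x = np.stack([b[0] for b in batch])[:, None]
            y = np.stack([b[1] for b in batch])[:, None]
            logits = model.forward(x, train=True)
            loss, dlogits = _bce_dice_from_logits(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        # validation (and checkpointing) every other epoch and on the last:
        # a full-resolution validation pass costs as much as an epoch of
        # crop-level training steps
        check = epoch % 2 == 1 or epoch == config.max_epochs - 1
        val_loss = _epoch_loss(model, val_pairs, config.depth) if val_pairs and check else None
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if check:
            monitored = val_loss if val_pairs else train_loss
            if monitored < best_val:
                best_val = monitored
                best_state = model.state()
    model.load_state(best_state)
    return ModelBundle(model, config, use_dilation, history, rng_seed=config.rng_seed)


def train_zoo(
    train_set,
    val_set,
    config: NetConfig | None = None,
    n_inits: int = 5,
    dilation_options: tuple[bool, ...] = (False, True),
    factor: int = 4,
    seed_size: int = 2,
    augment: AugmentConfig | None = None,
    crops_per_image: int = 1,
) -> list[ModelBundle]:
    """Train ``n_inits`` models per dilation option with distinct seeds."""
    if n_inits < 1:
        raise ValueError("n_inits must be >= 1")
    config = config or NetConfig()
    bundles = []
    for opt_idx, use_dilation in enumerate(dilation_options):
        for init in range(n_inits):
            seq = np.random.SeedSequence(config.rng_seed, spawn_key=(opt_idx, init))
            seed = int(seq.generate_state(1)[0] % (2**31))
            cfg = NetConfig(**{**config.__dict__, "rng_seed": seed})
            bundles.append(
                train_model(
                    train_set, val_set, cfg, use_dilation, factor, seed_size, augment,
                    crops_per_image,
                )
            )
    return bundles


def predict(model: UNet | ModelBundle, image: np.ndarray) -> np.ndarray:
    """Seed probability map for a normalized, upsampled image.

    The input is reflect-padded to a multiple of ``2**depth`` and the output
    cropped back, so any spatial size works.  Inference is deterministic.
    """
    net = model.model if isinstance(model, ModelBundle) else model
    x, orig = _pad_to_multiple(np.asarray(image, dtype=float), 2**net.depth)
    logits = net.forward(x[None, None], train=False)[0, 0]
    prob = 1.0 / (1.0 + np.exp(-logits[: orig[0], : orig[1]].astype(np.float64)))
    return np.clip(prob, EPS, 1.0 - EPS)


def detect_beads(
    model: UNet | ModelBundle,
    image: np.ndarray,
    factor: int = 4,
    threshold: float = 0.5,
    min_size: int = 1,
) -> DetectionSet:
    """Full inference on an original-resolution image.

    Normalize -> upsample -> predict -> threshold at 0.5 -> connected
    components -> centroids.  Coordinates are in the upsampled frame.
    """
    up = preprocess.upsample_bilinear(
        preprocess.normalize_intensity(image), preprocess.UpsampleSpec(factor)
    )
    return detections_from_probability(predict(model, up), threshold, min_size)


def select_model(
    bundles: list[ModelBundle],
    eval_set,
    factor: int = 4,
    enlargement_halfwidth: int = 3,
    border_margin: int = 4,
) -> ModelBundle:
    """Pick the bundle with the best detection F-score on ``eval_set``.

    Runs the full inference + evaluation pipeline per bundle; ties on Q_F
    are broken by lower Q_add, then by lower bundle index.  Each bundle's
    ``selection_score`` is filled with its Q_F.
    """
    if not bundles:
        raise ValueError("no bundles to select from")
    best_idx, best_key = 0, None
    for i, bundle in enumerate(bundles):
        report, _ = evaluation.evaluate_detector(
            eval_set,
            lambda img, b=bundle: detect_beads(b, img, factor),
            factor=factor,
            enlargement_halfwidth=enlargement_halfwidth,
            border_margin=border_margin,
        )
        bundle.selection_score = report.Q_F
        key = (-report.Q_F, report.Q_add, i)
        if best_key is None or key < best_key:
            best_key, best_idx = key, i
    return bundles[best_idx]


# -------------------------------------------------------- serialization ----


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    """Weights to ``<path>.npz``, config/history to ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = bundle.model.state()
    np.savez(path.with_suffix(".npz"), **{f"a{i:04d}": a for i, a in enumerate(arrays)})
    meta = {
        "config": bundle.config.__dict__,
        "dilation_used": bundle.dilation_used,
        "history": bundle.history,
        "rng_seed": bundle.rng_seed,
        "selection_score": bundle.selection_score,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> ModelBundle:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = NetConfig(**meta["config"])
    model = build_detector(config)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state([data[k] for k in sorted(data.files)])
    return ModelBundle(
        model,
        config,
        meta["dilation_used"],
        meta["history"],
        meta["rng_seed"],
        meta["selection_score"],
    )
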