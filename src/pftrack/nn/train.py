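"""Training loop and geometric data augmentation for the patch classifier.

Defaults follow the published recipe: Adam, binary cross-entropy, learning
rate 1e-4, batch size 2, 60 epochs, source pairs augmented to 15,000 variants
(rotation/zoom/shift 0.5, shear 0.2, both flips, zero fill), patches resized
to 112 x 112 for training. `rotation_unit` exists because a bare "0.5" is a
near-no-op in degrees but a 28.6-degree swing in radians; the default is
degrees, the native unit of the augmentation generator the recipe names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .layers import Adam, bce_with_logits
from .unet import UNet, normalize_intensity


@dataclass
class AugmentationConfig:
    rotation_range: float = 0.5   # +- range, unit per rotation_unit
    rotation_unit: str = "deg"    # "deg" or "rad"
    zoom_range: float = 0.5       # zoom factor sampled in [1 - z, 1 + z]
    shift_range: float = 0.5      # +- fraction of the patch size, both axes
    shear_range: float = 0.2      # +- degrees
    hflip: bool = True
    vflip: bool = True

    def validate(self) -> None:
        if min(self.rotation_range, self.zoom_range, self.shift_range, self.shear_range) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.rotation_unit not in ("deg", "rad"):
            raise ValueError("rotation_unit must be 'deg' or 'rad'")
        if self.zoom_range >= 1.0:
            raise ValueError("zoom_range must be < 1")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 60
    augmented_total: int = 15000
    aug: AugmentationConfig = field(default_factory=AugmentationConfig)
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs, self.augmented_total) <= 0:
            raise ValueError("all training hyperparameters must be positive")
        self.aug.validate()


def sample_transform(shape: tuple[int, int], aug: AugmentationConfig,
                     rng: np.random.Generator):
    """Sample one geometric transform: (AffineTransform, hflip, vflip).

    The affine part is centered on the patch center.
    """
    rot = rng.uniform(-aug.rotation_range, aug.rotation_range)
    if aug.rotation_unit == "deg":
        rot = np.deg2rad(rot)
    zoom = 1.0 + rng.uniform(-aug.zoom_range, aug.zoom_range)
    shear = np.deg2rad(rng.uniform(-aug.shear_range, aug.shear_range))
    h, w = shape
    shift = (rng.uniform(-aug.shift_range, aug.shift_range) * w,
             rng.uniform(-aug.shift_range, aug.shift_range) * h)
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(rotation=rot, shear=shear, scale=(zoom, zoom))
          + AffineTransform(translation=center + np.asarray(shift)))
    flips = (aug.hflip and bool(rng.integers(2)), aug.vflip and bool(rng.integers(2)))
    return tf, flips


def apply_transform(image: np.ndarray, mask: np.ndarray, tf, flips):
    """Apply the same sampled transform to image and mask; re-binarize the mask."""
    img = warp(image.astype(float), tf.inverse, order=1, mode="constant", cval=0.0,
               preserve_range=True)
    msk = warp(mask.astype(float), tf.inverse, order=1, mode="constant", cval=0.0,
               preserve_range=True)
    if flips[0]:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if flips[1]:
        img, msk = img[::-1, :], msk[::-1, :]
    return img.astype(np.float32), (msk >= 0.5).astype(np.uint8)


def augment_pairs(pairs, aug: AugmentationConfig, total: int, seed: int = 0):
    """Expand source pairs into exactly `total` transformed variants.

    Sources are cycled round-robin so each contributes total/len(pairs)
    variants (the published sets go 150 -> 15,000). Image and mask receive the
    SAME transform; masks are re-binarized at 0.5 after interpolation.
    """
    from ..simulate import TrainingPair

    pairs = list(pairs)
    if not pairs:
        raise ValueError("augment_pairs needs at least one source pair")
    aug.validate()
    rng = np.random.default_rng(seed)
    out = []
    for k in range(total):
        src = pairs[k % len(pairs)]
        tf, flips = sample_transform(src.image.shape, aug, rng)
        img, msk = apply_transform(src.image, src.mask, tf, flips)
        out.append(TrainingPair(img, msk, source_id=f"{src.source_id}#aug{k}"))
    return out


def _to_model_size(pair, input_px: int, span_floor: float = 0.0):
    # pair images live on [0, 1], so the fractional floor applies directly
    img = normalize_intensity(pair.image, span_floor)
    if img.shape != (input_px, input_px):
        img = resize(img, (input_px, input_px), order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
        msk = resize(pair.mask.astype(float), (input_px, input_px), order=1,
                     anti_aliasing=False, preserve_range=True) >= 0.5
    else:
        msk = pair.mask >= 0.5
    return img, msk.astype(np.float32)


def train(model: UNet, pairs, cfg: TrainConfig) -> dict:
    """Train on augmented pairs; returns {'loss': [...], 'val_loss': [...]}.

    Source pairs are split into train/validation BEFORE augmentation (90/10 by
    default) so no augmented variant of a validation patch leaks into
    training. All patches are min-max normalized and resized to the model's
    input resolution. Deterministic for a fixed seed on a fixed backend.
    """
    cfg.validate()
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 source pairs")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    n_val = int(round(cfg.val_fraction * len(pairs)))
    val_src = [pairs[i] for i in order[:n_val]]
    train_src = [pairs[i] for i in order[n_val:]]

    augmented = augment_pairs(train_src, cfg.aug, cfg.augmented_total,
                              seed=int(rng.integers(2 ** 31)))
    px = model.config.input_px
    floor = model.config.norm_span_floor
    xs, ys = zip(*(_to_model_size(p, px, floor) for p in augmented))
    x = np.stack(xs)[..., None]
    y = np.stack(ys)[..., None]
    if val_src:
        xv, yv = zip(*(_to_model_size(p, px, floor) for p in val_src))
        xval, yval = np.stack(xv)[..., None], np.stack(yv)[..., None]

    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = {"loss": [], "val_loss": []}
    n = x.shape[0]
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n - n % cfg.batch_size, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            losses.append(model.train_step(x[idx], y[idx], opt))
        history["loss"].append(float(np.mean(losses)))
        if val_src:
            z = model.forward_logits(xval.astype(model.dtype))
            vloss, _, _ = bce_with_logits(z, yval)
            history["val_loss"].append(vloss)
    return history
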