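"""U-Net patch classifier whose class-1 probability is the pseudofluorescence signal.

Classic encoder-decoder with skip connections: `depth` resolution levels, a
double 3x3 conv + ReLU block per level, 2x max-pooling down, 2x2 transposed
convolutions up, and a 1-channel sigmoid head. Channel width doubles per level
from `base_filters`. Weights are He-initialized from the config seed, so a
fixed config gives a bit-reproducible model. Arrays are NHWC float32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .layers import (
    DTYPE, Adam, Conv2d, ConvTranspose2, MaxPool2, ReLU, bce_with_logits, sigmoid,
)


@dataclass
class UNetConfig:
    depth: int = 5            # resolution levels of the U
    base_filters: int = 16    # channels at the top level; doubles per level
    input_px: int = 112       # square input size the net is trained at
    kernel: int = 3
    in_channels: int = 1
    #: window-normalization span floor as a fraction of the data range: windows
    #: whose dynamic range is below this (pure background) are NOT stretched to
    #: full contrast, which would amplify noise into cell-like structure
    norm_span_floor: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_px % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_px={self.input_px} not divisible by 2^(depth-1)={2 ** (self.depth - 1)}"
            )


class _DoubleConv:
    def __init__(self, c_in, c_out, k, rng, dtype):
        self.ops = [Conv2d(c_in, c_out, k, rng, dtype), ReLU(),
                    Conv2d(c_out, c_out, k, rng, dtype), ReLU()]

    def forward(self, x, train=False):
        for op in self.ops:
            x = op.forward(x, train)
        return x

    def backward(self, dy):
        for op in reversed(self.ops):
            dy = op.backward(dy)
        return dy

    def params(self):
        return [p for op in self.ops for p in op.params()]


class UNet:
    """Binary segmentation network; predict() maps patches to cell probability."""

    def __init__(self, config: UNetConfig, dtype=DTYPE):
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        f = [config.base_filters * 2 ** i for i in range(config.depth)]
        self.enc = []
        c_prev = config.in_channels
        for c in f:
            self.enc.append(_DoubleConv(c_prev, c, k, rng, dtype))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(config.depth - 1)]
        self.ups = []
        self.dec = []
        for i in range(config.depth - 2, -1, -1):
            self.ups.append(ConvTranspose2(f[i + 1], f[i], rng, dtype))
            self.dec.append(_DoubleConv(2 * f[i], f[i], k, rng, dtype))
        self.head = Conv2d(f[0], 1, 1, rng, dtype)

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, 1) -> logits (N, H, W, 1)."""
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dz: np.ndarray) -> None:
        dy = self.head.backward(dz)
        # decoder stages unwind top-down, so dskips[i] lines up with skips[i]
        dskips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec)):
            dy = block.backward(dy)
            c_skip = up.c_out
            dskips.append(np.ascontiguousarray(dy[..., :c_skip]))
            dy = up.backward(np.ascontiguousarray(dy[..., c_skip:]))
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: Adam) -> float:
        opt.zero_grad()
        z = self.forward_logits(x, train=True)
        loss, dz, _ = bce_with_logits(z, y)
        self.backward(dz)
        opt.step()
        return loss

    # -- inference ---------------------------------------------------------
    def predict(self, x: np.ndarray, chunk: int = 8) -> np.ndarray:
        """Batch of patches (N, H, W) or (N, H, W, 1) -> probabilities (N, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        out = np.empty(x.shape[:3], dtype=self.dtype)
        for i in range(0, x.shape[0], chunk):
            z = self.forward_logits(x[i:i + chunk], train=False)
            out[i:i + chunk] = sigmoid(z)[..., 0]
        return out

    # -- bookkeeping -------------------------------------------------------
    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        for up in self.ups:
            out += up.params()
        for block in self.dec:
            out += block.params()
        out += self.head.params()
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    def save_weights(self, path: str | Path, extra_meta: dict | None = None) -> None:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, **arrays)
        meta = {"unet": asdict(self.config)}
        if extra_meta:
            meta.update(extra_meta)
        self._sidecar(path).write_text(json.dumps(meta, indent=2))

    @staticmethod
    def _sidecar(path: Path) -> Path:
        return path.with_suffix(path.suffix + ".json")

    @classmethod
    def load_weights(cls, path: str | Path, config: UNetConfig | None = None) -> "UNet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        if config is None:
            sidecar = cls._sidecar(path)
            if not sidecar.exists():
                raise FileNotFoundError(f"no config sidecar at {sidecar}")
            config = UNetConfig(**json.loads(sidecar.read_text())["unet"])
        model = cls(config)
        with np.load(path) as data:
            stored = [data[f"p{i}"] for i in range(len(data.files))]
        own = model.state_arrays()
        if len(stored) != len(own):
            raise ValueError(
                f"weight count mismatch: file has {len(stored)}, model needs {len(own)}")
        for tgt, src in zip(own, stored):
            if tgt.shape != src.shape:
                raise ValueError(f"weight shape mismatch: {src.shape} vs expected {tgt.shape}")
            tgt[...] = src
        return model


def normalize_intensity(window: np.ndarray, span_floor: float = 0.0) -> np.ndarray:
    """Per-window min-max rescale to [0, 1]; a constant window maps to zeros.

    Makes prediction invariant to additive intensity shifts of the raw image,
    which is what lets one trained model cope with illumination offsets.
    `span_floor` (in the window's own intensity units) caps the stretch: a
    window whose dynamic range is below the floor — pure background — keeps a
    proportionally low contrast instead of having its noise amplified to full
    scale. The floor leaves windows with real content untouched.
    """
    window = np.asarray(window, dtype=DTYPE)
    lo = window.min()
    span = max(window.max() - lo, span_floor)
    if span == 0:
        return np.zeros_like(window)
    return (window - lo) / DTYPE(span)


def build_model(config: UNetConfig) -> UNet:
    return UNet(config)


def predict_window(model: UNet, window: np.ndarray, data_range: float = 1.0) -> np.ndarray:
    """Predict cell probability for one window of arbitrary square size.

    The window is min-max normalized (with the model's span floor, scaled by
    `data_range` — 1.0 for [0, 1] images, 255 for 8-bit counts) and resized to
    the model's training resolution; the probability patch is resized back.
    """
    from skimage.transform import resize

    win = normalize_intensity(window, model.config.norm_span_floor * data_range)
    px = model.config.input_px
    if win.shape != (px, px):
        win = resize(win, (px, px), order=1, anti_aliasing=False, preserve_range=True)
    prob = model.predict(win[None].astype(DTYPE))[0]
    if prob.shape != window.shape:
        prob = resize(prob, window.shape, order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(prob, 0.0, 1.0).astype(DTYPE)
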