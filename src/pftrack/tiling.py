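"""Sliding-window decomposition and seamless reassembly of probability maps.

Full frames are cut into 56 x 56 px windows, each window is upscaled 4x for
the patch classifier, and the per-window class-1 probabilities are downscaled
and stitched back into a full-frame pseudofluorescence channel. With the
default stride equal to the window the tiles are disjoint and reassembly is an
exact paste; with overlap (e.g. stride = window/2) contributions are blended
with a raised-cosine weight to suppress seam artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .imgio import ImageStack


@dataclass
class TilePlan:
    frame_shape: tuple[int, int]
    window_px: int = 56
    stride_px: int = 56
    pad_mode: str = "reflect"  # reflect | zero
    tiles: list[tuple[int, int]] = None  # (row0, col0) origins, row-major

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


def _axis_origins(dim: int, window: int, stride: int) -> list[int]:
    """Tile origins along one axis; the last origin is clamped so its tile
    ends at the frame edge (padding only when the frame is smaller than one
    window)."""
    if dim <= window:
        return [0]
    origins = list(range(0, dim - window, stride))
    last = dim - window
    if origins[-1] != last:
        origins.append(last)
    return origins


def plan_tiles(frame_shape: tuple[int, int], window_px: int = 56, stride_px: int | None = None,
               pad_mode: str = "reflect") -> TilePlan:
    """Row-major tile origins covering every pixel of the frame."""
    if stride_px is None:
        stride_px = window_px
    if window_px <= 0:
        raise ValueError("window_px must be positive")
    if not 0 < stride_px <= window_px:
        raise ValueError(f"stride_px must be in (0, window_px]; "
                         f"stride {stride_px} > window {window_px} would leave holes")
    if pad_mode not in ("reflect", "zero"):
        raise ValueError(f"unknown pad_mode {pad_mode!r}")
    h, w = frame_shape
    tiles = [(r, c) for r in _axis_origins(h, window_px, stride_px)
             for c in _axis_origins(w, window_px, stride_px)]
    return TilePlan(tuple(frame_shape), window_px, stride_px, pad_mode, tiles)


def extract_window(frame: np.ndarray, origin: tuple[int, int], window_px: int,
                   pad_mode: str = "reflect") -> np.ndarray:
    """window_px x window_px crop at `origin`; out-of-frame pixels are padded."""
    r0, c0 = origin
    h, w = frame.shape
    r1, c1 = r0 + window_px, c0 + window_px
    if 0 <= r0 and 0 <= c0 and r1 <= h and c1 <= w:
        return frame[r0:r1, c0:c1]
    pad_h = max(0, r1 - h)
    pad_w = max(0, c1 - w)
    mode = "reflect" if pad_mode == "reflect" else "constant"
    padded = np.pad(frame, ((0, pad_h), (0, pad_w)), mode=mode)
    return padded[r0:r1, c0:c1]


def upscale_window(window: np.ndarray, factor: int = 4) -> np.ndarray:
    """Bilinear upscaling by an integer factor (56 -> 224 for the default)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return np.asarray(window)
    out_shape = (window.shape[0] * factor, window.shape[1] * factor)
    return resize(np.asarray(window, dtype=np.float32), out_shape, order=1,
                  anti_aliasing=False, preserve_range=True).astype(np.float32)


def downscale_probability(prob_window: np.ndarray, factor: int = 4) -> np.ndarray:
    """Block-mean (area) downsampling of a probability patch; mass-preserving."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    prob_window = np.asarray(prob_window)
    h, w = prob_window.shape
    if h % factor or w % factor:
        raise ValueError(f"side {prob_window.shape} not divisible by factor {factor}")
    if factor == 1:
        return prob_window
    return prob_window.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _hann2d(n: int) -> np.ndarray:
    # offset Hann: strictly positive so single-tile pixels keep their value
    w = 0.5 - 0.5 * np.cos(2.0 * np.pi * (np.arange(n) + 0.5) / n)
    return np.outer(w, w) + 1e-6


def reassemble(tile_probs: list[np.ndarray], plan: TilePlan) -> np.ndarray:
    """Stitch per-tile probability patches into one full-frame map in [0, 1].

    Disjoint plans (stride == window) paste exactly (bit-preserving);
    overlapping plans blend with a Hann weight per tile.
    """
    if len(tile_probs) != plan.n_tiles:
        raise ValueError(f"expected {plan.n_tiles} patches, got {len(tile_probs)}")
    h, w = plan.frame_shape
    n = plan.window_px
    if plan.stride_px == plan.window_px and all(
            r + n <= h and c + n <= w for r, c in plan.tiles):
        out = np.zeros((h, w), dtype=np.asarray(tile_probs[0]).dtype)
        # reverse order so earlier (canonical) tiles win where clamped tiles touch
        for (r, c), patch in reversed(list(zip(plan.tiles, tile_probs))):
            out[r:r + n, c:c + n] = patch
        return np.clip(out, 0.0, 1.0)
    acc = np.zeros((h + n, w + n))
    weight = np.zeros((h + n, w + n))
    hann = _hann2d(n)
    for (r, c), patch in zip(plan.tiles, tile_probs):
        acc[r:r + n, c:c + n] += hann * patch
        weight[r:r + n, c:c + n] += hann
    out = acc[:h, :w] / np.maximum(weight[:h, :w], 1e-12)
    return np.clip(out, 0.0, 1.0)


def convert_frame(frame: np.ndarray, model, window_px: int = 56, upscale_factor: int = 4,
                  stride_px: int | None = None, pad_mode: str = "reflect",
                  data_range: float = 255.0) -> np.ndarray:
    """TL frame -> pseudofluorescence probability map (same shape, [0, 1]).

    Each window is min-max normalized (span floor scaled by `data_range`, the
    full scale of the input's intensity units), upscaled, resized to the
    model's input resolution, classified, and the probability patch downscaled
    back; patches are stitched per the tile plan. Windows are batched through
    the network.
    """
    from .nn.unet import normalize_intensity

    plan = plan_tiles(frame.shape, window_px, stride_px, pad_mode)
    up_px = window_px * upscale_factor
    in_px = model.config.input_px
    span_floor = model.config.norm_span_floor * data_range
    batch = np.empty((plan.n_tiles, in_px, in_px), dtype=np.float32)
    for i, origin in enumerate(plan.tiles):
        win = normalize_intensity(extract_window(frame, origin, window_px, pad_mode),
                                  span_floor)
        up = upscale_window(win, upscale_factor)
        if up_px != in_px:
            up = resize(up, (in_px, in_px), order=1, anti_aliasing=False,
                        preserve_range=True).astype(np.float32)
        batch[i] = up
    probs = model.predict(batch)
    patches = []
    for i in range(plan.n_tiles):
        p = probs[i]
        if in_px != up_px:
            p = resize(p, (up_px, up_px), order=1, anti_aliasing=False,
                       preserve_range=True)
        patches.append(downscale_probability(p, upscale_factor))
    return reassemble(patches, plan).astype(np.float32)


def convert_stack(stack: ImageStack, model, window_px: int = 56, upscale_factor: int = 4,
                  stride_px: int | None = None, pad_mode: str = "reflect") -> ImageStack:
    """Convert a whole TL stack into the pseudofluorescence channel.

    Output frames hold probabilities in [0, 1]; writing through
    `imgio.write_stack` maps 1.0 to the maximum code value of the bit depth.
    """
    data_range = float(2 ** stack.bit_depth - 1)
    out = np.empty(stack.data.shape, dtype=np.float32)
    for t in range(stack.n_frames):
        out[t] = convert_frame(stack.data[t].astype(np.float32), model, window_px,
                               upscale_factor, stride_px, pad_mode, data_range)
    return stack.with_data(out, channel_name="pseudofluorescence")
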