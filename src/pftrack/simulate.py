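"""Synthetic wide-chamber time-lapse microscopy with ground truth.

Emulates the imaging regime of low-magnification widefield chemotaxis assays:
few pixels per cell (8 µm cells at 1.62 µm/px), transmitted-light contrast
close to background, defocus-dependent appearance changes, a linear
illumination gradient, shot + read noise, and an optional photobleaching
fluorescence channel. Every render is a pure function of (config, seed), and
per-frame RNG streams are derived independently so earlier frames never change
when `n_frames` grows.

The transmitted-light cell profile is the zero-mean ring
P(d) = ((d^2 - 2)/2) * exp(-d^2/2) of the elliptical Mahalanobis radius d:
dark core, bright rim, and (for the default sigma = diameter/4) zero net flux
over the plane, so mean cell intensity stays close to background — the
low-SNR challenge the pipeline exists for. Ground-truth masks are the
ellipses d <= 2, i.e. the stated cell diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .imgio import ImageStack
from .tracks import Spot, Track, um_to_px


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class MotilityModel:
    """Persistent random walk with optional chemotactic drift.

    The intrinsic velocity follows v_t = p * v_{t-1} + (1 - p) * w_t with w_t a
    random step of speed ~ N(mean, sd) (truncated to [0, mean + 4 sd]) in a
    uniform direction; the per-frame displacement is v_t + drift. By induction
    |v_t| never exceeds (mean + 4 sd) * frame_interval.
    """

    speed_um_per_s_mean: float = 0.08
    speed_um_per_s_sd: float = 0.03
    persistence: float = 0.7
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0)


@dataclass
class FocusModel:
    """Defocus model: z excursions are limited to roughly the depth of field of
    a low-NA air objective (±6 µm), and the per-frame z step is fast enough
    that a cell's focus state decorrelates within a few frames — emulating the
    per-timepoint autofocus jitter of long acquisitions."""

    z_range_um: float = 12.0           # cells wander within +- z_range/2 of focus
    blur_sigma_um_per_um: float = 0.1  # PSF sigma growth per µm of defocus
    z_step_fraction: float = 0.125     # per-frame z walk sd as fraction of z_range


@dataclass
class IlluminationModel:
    gradient_amplitude: float = 0.1   # fractional peak-to-center amplitude


@dataclass
class NoiseModel:
    gaussian_sd: float = 1.5    # read noise, intensity counts
    poisson_scale: float = 0.15  # shot-noise gain; sd = sqrt(I * scale); 0 disables


@dataclass
class SceneConfig:
    field_size_px: tuple[int, int] = (256, 256)  # (height, width)
    pixel_size_um: float = 1.62
    frame_interval_s: float = 20.0
    n_frames: int = 90
    n_cells: int = 15
    # clonal cultured lines are narrowly distributed in size (CV ~6%); large
    # outliers would mismatch the fixed spot-diameter convention of trackers
    cell_diameter_um_mean: float = 8.0
    cell_diameter_um_sd: float = 0.5
    morphology: str = "round"  # round | elongated | mixed
    motility: MotilityModel = field(default_factory=MotilityModel)
    focus: FocusModel = field(default_factory=FocusModel)
    illumination: IlluminationModel = field(default_factory=IlluminationModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    bleach_tau_s: float | None = None
    contrast: float = 1.0              # signed; >0 = dark core / bright rim
    #: per-frame multiplicative jitter of each cell's TL appearance (shape and
    #: scattering changes between timepoints); fluorescence is not affected
    tl_intensity_jitter_sd: float = 0.1
    background_level: float = 100.0
    fluorescence_amplitude: float = 120.0
    fluorescence_background: float = 10.0
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        h, w = self.field_size_px
        if h < 1 or w < 1:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.cell_diameter_um_mean <= 0:
            raise ValueError("cell diameter must be positive")
        if self.morphology not in ("round", "elongated", "mixed"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if not 0.0 <= self.motility.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if not 0.0 <= self.illumination.gradient_amplitude < 1.0:
            raise ValueError("illumination gradient amplitude must be in [0, 1)")
        if self.bleach_tau_s is not None and self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive or None")

    @property
    def field_extent_um(self) -> tuple[float, float]:
        """(width, height) in µm."""
        h, w = self.field_size_px
        return (w * self.pixel_size_um, h * self.pixel_size_um)


# --------------------------------------------------------------------------
# scene
# --------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SyntheticScene:
    """Ground-truth cell states per frame plus rendered truth masks and tracks."""

    config: SceneConfig
    positions_um: np.ndarray     # (T, n_cells, 2): x, y
    orientations: np.ndarray     # (T, n_cells) radians
    sigmas_um: np.ndarray        # (n_cells, 2): major, minor Gaussian sigma
    z_offsets_um: np.ndarray     # (T, n_cells)
    base_intensity: np.ndarray   # (n_cells,) multiplicative brightness
    truth_masks: np.ndarray      # (T, Y, X) uint8 in {0, 1}
    label_masks: np.ndarray      # (T, Y, X) int32, 0 = background, cell id + 1
    truth_tracks: list[Track]

    @property
    def n_cells(self) -> int:
        return self.positions_um.shape[1]


def simulate_scene(config: SceneConfig) -> SyntheticScene:
    """Run the motility model and rasterize ground-truth masks and tracks."""
    config.validate()
    h, w = config.field_size_px
    n, t_total = config.n_cells, config.n_frames
    extent = np.array(config.field_extent_um)  # (x, y)
    mot = config.motility
    dt = config.frame_interval_s

    init = _rng(config.seed, 0)
    sigmas = np.zeros((n, 2))
    base_int = np.ones(n)
    positions = np.zeros((t_total, n, 2))
    orientations = np.zeros((t_total, n))
    z = np.zeros((t_total, n))
    if n:
        diam = np.clip(init.normal(config.cell_diameter_um_mean, config.cell_diameter_um_sd, n),
                       2.0 * config.pixel_size_um, None)
        sigma_eq = diam / 4.0
        if config.morphology == "round":
            ratio = np.ones(n)
        elif config.morphology == "elongated":
            ratio = init.uniform(2.5, 5.0, n)
        else:
            ratio = np.where(init.random(n) < 0.5, 1.0, init.uniform(2.5, 5.0, n))
        sigmas[:, 0] = sigma_eq * np.sqrt(ratio)
        sigmas[:, 1] = sigma_eq / np.sqrt(ratio)
        base_int = np.clip(init.normal(1.0, 0.1, n), 0.5, 1.5)
        positions[0] = _place_without_overlap(init, n, diam, extent)
        orientations[0] = init.uniform(0, 2 * np.pi, n)
        z[0] = init.uniform(-config.focus.z_range_um / 2, config.focus.z_range_um / 2, n)

    s_max = (mot.speed_um_per_s_mean + 4.0 * mot.speed_um_per_s_sd) * dt
    drift = np.asarray(mot.drift_um_per_frame)
    v = np.zeros((n, 2))
    for t in range(1, t_total):
        rng = _rng(config.seed, 1, t)
        speed = np.clip(rng.normal(mot.speed_um_per_s_mean, mot.speed_um_per_s_sd, n),
                        0.0, None) * dt
        speed = np.minimum(speed, s_max)
        theta = rng.uniform(0, 2 * np.pi, n)
        wstep = speed[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        v = mot.persistence * v + (1.0 - mot.persistence) * wstep
        pos, v = _reflect(positions[t - 1] + v + drift, v, extent)
        positions[t] = pos
        orientations[t] = orientations[t - 1] + \
            (1.0 - mot.persistence) * rng.normal(0.0, 0.3, n)
        zr = config.focus.z_range_um
        z[t] = np.clip(z[t - 1] + rng.normal(0.0, zr * config.focus.z_step_fraction, n),
                       -zr / 2, zr / 2)

    truth_masks = np.zeros((t_total, h, w), dtype=np.uint8)
    label_masks = np.zeros((t_total, h, w), dtype=np.int32)
    for t in range(t_total):
        _rasterize_masks(config, positions[t], orientations[t], sigmas,
                         truth_masks[t], label_masks[t])

    tracks = []
    for c in range(n):
        spots = [Spot(frame=t, x_um=float(positions[t, c, 0]), y_um=float(positions[t, c, 1]),
                      quality=1.0) for t in range(t_total)]
        tracks.append(Track(id=c, spots=spots))
    return SyntheticScene(config, positions, orientations, sigmas, z, base_int,
                          truth_masks, label_masks, tracks)


def _place_without_overlap(rng, n, diam, extent, max_tries: int = 2000):
    pos = np.zeros((n, 2))
    for i in range(n):
        for _ in range(max_tries):
            cand = rng.random(2) * extent
            if all(np.linalg.norm(cand - pos[j]) >= 0.6 * (diam[i] + diam[j])
                   for j in range(i)):
                pos[i] = cand
                break
        else:  # dense field: accept overlap rather than fail
            pos[i] = rng.random(2) * extent
    return pos


def _reflect(pos, v, extent):
    """Reflect positions (and flip velocities) at the field borders."""
    pos = pos.copy()
    v = v.copy()
    for ax in range(2):
        lo = pos[:, ax] < 0
        pos[lo, ax] = -pos[lo, ax]
        v[lo, ax] = -v[lo, ax]
        hi = pos[:, ax] > extent[ax]
        pos[hi, ax] = 2 * extent[ax] - pos[hi, ax]
        v[hi, ax] = -v[hi, ax]
    # a step larger than the field could still be outside; clamp defensively
    np.clip(pos, 0.0, extent, out=pos)
    return pos, v


def _cell_grid(config, pos_um, sigma_px_max, blur_px, shape):
    """Local patch bounds and pixel-center grid around one cell."""
    h, w = shape
    cx, cy = um_to_px(pos_um, config.pixel_size_um)
    half = int(np.ceil(4.0 * sigma_px_max + 3.0 * blur_px)) + 2
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (y0, y1, x0, x1), (xx - cx), (yy - cy)


def _mahalanobis_sq(dx_px, dy_px, orientation, sigma_major_px, sigma_minor_px):
    c, s = np.cos(orientation), np.sin(orientation)
    u = (c * dx_px + s * dy_px) / sigma_major_px
    t = (-s * dx_px + c * dy_px) / sigma_minor_px
    return u * u + t * t


def _rasterize_masks(config, pos, ori, sigmas_um, mask_out, label_out):
    px = config.pixel_size_um
    best = np.full(mask_out.shape, np.inf)
    for c in range(pos.shape[0]):
        smaj, smin = sigmas_um[c] / px
        grid = _cell_grid(config, pos[c], smaj, 0.0, mask_out.shape)
        if grid is None:
            continue
        (y0, y1, x0, x1), dx, dy = grid
        d2 = _mahalanobis_sq(dx, dy, ori[c], smaj, smin)
        inside = d2 <= 4.0
        mask_out[y0:y1, x0:x1][inside] = 1
        claim = inside & (d2 < best[y0:y1, x0:x1])
        label_out[y0:y1, x0:x1][claim] = c + 1
        best[y0:y1, x0:x1][claim] = d2[claim]


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _background(config) -> np.ndarray:
    h, w = config.field_size_px
    amp = config.illumination.gradient_amplitude
    gx = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(w)
    gy = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(h)
    plane = 1.0 + amp * 0.5 * (gx[None, :] + gy[:, None])
    return config.background_level * plane


def _apply_noise(frame, rng, noise: NoiseModel) -> np.ndarray:
    if noise.poisson_scale > 0:
        frame = rng.poisson(np.clip(frame, 0, None) / noise.poisson_scale) * noise.poisson_scale
    if noise.gaussian_sd > 0:
        frame = frame + rng.normal(0.0, noise.gaussian_sd, frame.shape)
    return frame


def render_tl(scene: SyntheticScene) -> ImageStack:
    """Render the transmitted-light channel (low contrast by construction)."""
    config = scene.config
    px = config.pixel_size_um
    frames = np.zeros((config.n_frames,) + tuple(config.field_size_px), dtype=np.float32)
    bg = _background(config)
    for t in range(config.n_frames):
        rng = _rng(config.seed, 2, t)
        jitter = 1.0 + rng.normal(0.0, config.tl_intensity_jitter_sd, max(scene.n_cells, 1))
        frame = bg.copy()
        for c in range(scene.n_cells):
            smaj, smin = scene.sigmas_um[c] / px
            blur = config.focus.blur_sigma_um_per_um * abs(scene.z_offsets_um[t, c]) / px
            grid = _cell_grid(config, scene.positions_um[t, c], smaj, blur, frame.shape)
            if grid is None:
                continue
            (y0, y1, x0, x1), dx, dy = grid
            d2 = _mahalanobis_sq(dx, dy, scene.orientations[t, c], smaj, smin)
            profile = 0.5 * (d2 - 2.0) * np.exp(-0.5 * d2)
            patch = (config.contrast * config.background_level *
                     scene.base_intensity[c] * jitter[c] * profile)
            if blur > 0.05:
                patch = gaussian_filter(patch, blur, mode="constant")
            frame[y0:y1, x0:x1] += patch
        frame = _apply_noise(frame, rng, config.noise)
        frames[t] = np.clip(frame, 0.0, 255.0)
    return ImageStack(frames, px, config.frame_interval_s, "TL", config.bit_depth)


def render_fluorescence(scene: SyntheticScene) -> ImageStack:
    """Render the fluorescence channel with exponential photobleaching.

    Cell signal decays as I(t) = I(0) * exp(-t / bleach_tau_s); the background
    is unbleached. Noise is additive Gaussian only.
    """
    config = scene.config
    if config.bleach_tau_s is None:
        raise ValueError("render_fluorescence requires bleach_tau_s to be set")
    px = config.pixel_size_um
    frames = np.zeros((config.n_frames,) + tuple(config.field_size_px), dtype=np.float32)
    for t in range(config.n_frames):
        frame = np.full(config.field_size_px, config.fluorescence_background, dtype=float)
        decay = np.exp(-(t * config.frame_interval_s) / config.bleach_tau_s)
        for c in range(scene.n_cells):
            smaj, smin = scene.sigmas_um[c] / px
            blur = config.focus.blur_sigma_um_per_um * abs(scene.z_offsets_um[t, c]) / px
            grid = _cell_grid(config, scene.positions_um[t, c], smaj, blur, frame.shape)
            if grid is None:
                continue
            (y0, y1, x0, x1), dx, dy = grid
            d2 = _mahalanobis_sq(dx, dy, scene.orientations[t, c], smaj, smin)
            patch = (config.fluorescence_amplitude * scene.base_intensity[c] * decay *
                     np.exp(-0.5 * d2))
            if blur > 0.05:
                patch = gaussian_filter(patch, blur, mode="constant")
            region = frame[y0:y1, x0:x1]
            np.maximum(region, config.fluorescence_background + patch, out=region)
        rng = _rng(config.seed, 3, t)
        if config.noise.gaussian_sd > 0:
            frame = frame + rng.normal(0.0, config.noise.gaussian_sd, frame.shape)
        frames[t] = np.clip(frame, 0.0, 255.0)
    return ImageStack(frames, px, config.frame_interval_s, "fluorescence", config.bit_depth)


def mask_stack(scene: SyntheticScene) -> ImageStack:
    """Ground-truth masks as an image channel (values {0, 1})."""
    return ImageStack(scene.truth_masks, scene.config.pixel_size_um,
                      scene.config.frame_interval_s, "mask", 8)


# --------------------------------------------------------------------------
# training-pair export
# --------------------------------------------------------------------------

@dataclass
class TrainingPair:
    """One TL crop and its binary mask at matched scale."""

    image: np.ndarray   # float32 in [0, 1]
    mask: np.ndarray    # uint8 in {0, 1}
    source_id: str = ""

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def export_training_pairs(scene: SyntheticScene, n_pairs: int, crop_px: int = 56,
                          seed: int = 0, tl: ImageStack | None = None) -> list[TrainingPair]:
    """Random TL crops paired with the matching truth-mask crops.

    Roughly 60% of crops are centered on randomly chosen cells with jitter
    (annotators zoom in on cells); the rest are placed uniformly so that pure
    background — which the per-window normalization stretches to full
    contrast at inference time — is well represented in training. The crop's
    physical size for the defaults is 56 px * 1.62 µm/px = 90.72 µm.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    config = scene.config
    h, w = config.field_size_px
    if crop_px > h or crop_px > w:
        raise ValueError(f"crop_px={crop_px} exceeds field {config.field_size_px}")
    if tl is None:
        tl = render_tl(scene)
    rng = np.random.default_rng(seed)
    pairs = []
    for k in range(n_pairs):
        t = int(rng.integers(config.n_frames))
        if scene.n_cells and rng.random() >= 0.4:
            c = int(rng.integers(scene.n_cells))
            cx, cy = um_to_px(scene.positions_um[t, c], config.pixel_size_um)
            jitter = rng.uniform(-crop_px / 4, crop_px / 4, 2)
            x0 = int(round(cx + jitter[0] - crop_px / 2))
            y0 = int(round(cy + jitter[1] - crop_px / 2))
        else:
            x0 = int(rng.integers(w - crop_px + 1))
            y0 = int(rng.integers(h - crop_px + 1))
        x0 = min(max(x0, 0), w - crop_px)
        y0 = min(max(y0, 0), h - crop_px)
        img = tl.data[t, y0:y0 + crop_px, x0:x0 + crop_px].astype(np.float32) / 255.0
        msk = scene.truth_masks[t, y0:y0 + crop_px, x0:x0 + crop_px]
        pairs.append(TrainingPair(img, msk.copy(), source_id=f"t{t}_x{x0}_y{y0}_{k}"))
    return pairs


def write_training_pairs(pairs: list[TrainingPair], out_dir: str | Path) -> list[tuple[Path, Path]]:
    """Write pairs as 8-bit grayscale `<id>_img.png` / `<id>_mask.png` (mask {0, 255})."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, pair in enumerate(pairs):
        img_path = out_dir / f"{i:04d}_img.png"
        mask_path = out_dir / f"{i:04d}_mask.png"
        iio.imwrite(img_path, np.clip(pair.image * 255.0 + 0.5, 0, 255).astype(np.uint8))
        iio.imwrite(mask_path, (pair.mask * 255).astype(np.uint8))
        paths.append((img_path, mask_path))
    return paths


def read_training_pairs(in_dir: str | Path) -> list[TrainingPair]:
    """Read `<id>_img.png` / `<id>_mask.png` pairs (the released training-set layout)."""
    import imageio.v3 as iio

    in_dir = Path(in_dir)
    pairs = []
    for img_path in sorted(in_dir.glob("*_img.png")):
        mask_path = img_path.with_name(img_path.name.replace("_img.png", "_mask.png"))
        if not mask_path.exists():
            raise FileNotFoundError(mask_path)
        img = iio.imread(img_path).astype(np.float32) / 255.0
        msk = (iio.imread(mask_path) >= 128).astype(np.uint8)
        pairs.append(TrainingPair(img, msk, source_id=img_path.stem))
    if not pairs:
        raise ValueError(f"no *_img.png files in {in_dir}")
    return pairs


def write_truth_tracks(scene: SyntheticScene, path: str | Path) -> None:
    """Ground-truth track CSV with both physical and pixel coordinates."""
    import pandas as pd

    px = scene.config.pixel_size_um
    rows = []
    for tr in scene.truth_tracks:
        for s in tr.spots:
            rows.append((tr.id, s.frame, s.x_um, s.y_um,
                         float(um_to_px(s.x_um, px)), float(um_to_px(s.y_um, px))))
    pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "x_px", "y_px"]) \
        .to_csv(path, index=False, float_format="%.6g")
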