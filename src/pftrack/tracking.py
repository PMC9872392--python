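"""Spot detection and frame-to-frame linking on any image channel.

Reimplements the two detection routes used on the pseudofluorescence signal —
Laplacian-of-Gaussian blob detection and (automatic) threshold detection — and
a simple LAP linker: per-frame Hungarian assignment under a distance gate,
with no gap closing. Defaults follow the published tracking protocol: 8 µm
spot diameter, 20 µm maximum link distance, gap size 0, and exclusion of
tracks shorter than 300 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_laplace, label, sum_labels
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball

from .imgio import ImageStack
from .tracks import Spot, Track, px_to_um

_GATE_COST = 1e12


@dataclass
class TrackerConfig:
    spot_diameter_um: float = 8.0
    max_link_distance_um: float = 20.0
    max_gap_frames: int = 0           # only 0 is supported (no gap closing)
    min_track_duration_s: float = 300.0
    detector: str = "log"             # log | threshold
    detection_threshold: float | str = "auto"  # "auto" = Otsu with a noise floor
    noise_floor_sigmas: float = 5.0   # robust floor protecting "auto" on empty channels
    background_subtraction: bool = False
    rolling_ball_radius_um: float = 16.0
    roi_um: tuple[float, float, float, float] | None = None  # x0, y0, x1, y1

    def validate(self) -> None:
        if self.spot_diameter_um <= 0 or self.max_link_distance_um < 0:
            raise ValueError("distances must be non-negative")
        if self.min_track_duration_s < 0:
            raise ValueError("min_track_duration_s must be non-negative")
        if self.max_gap_frames != 0:
            raise ValueError("only max_gap_frames = 0 is supported (no gap closing)")
        if self.detector not in ("log", "threshold"):
            raise ValueError(f"unknown detector {self.detector!r}")


def subtract_background(frame: np.ndarray, radius_um: float, pixel_size_um: float) -> np.ndarray:
    """Rolling-ball background subtraction (non-uniform illumination removal)."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    frame = np.asarray(frame, dtype=float)
    radius_px = max(1.0, radius_um / pixel_size_um)
    background = rolling_ball(frame, radius=radius_px)
    return np.clip(frame - background, 0.0, None)


def _quadratic_subpixel(response: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Per-axis parabola fit around a local maximum; offsets clipped to +-0.5 px."""
    out = []
    for axis, idx in ((0, r), (1, c)):
        if idx == 0 or idx == response.shape[axis] - 1:
            out.append(0.0)
            continue
        if axis == 0:
            fm, f0, fp = response[r - 1, c], response[r, c], response[r + 1, c]
        else:
            fm, f0, fp = response[r, c - 1], response[r, c], response[r, c + 1]
        denom = fm - 2.0 * f0 + fp
        out.append(0.0 if denom == 0 else float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5)))
    return out[0], out[1]


def _spot_intensity(frame: np.ndarray, r: float, c: float, radius_px: float) -> float:
    h, w = frame.shape
    r0, r1 = max(0, int(r - radius_px)), min(h, int(r + radius_px) + 1)
    c0, c1 = max(0, int(c - radius_px)), min(w, int(c + radius_px) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disc = (yy - r) ** 2 + (xx - c) ** 2 <= radius_px ** 2
    if not disc.any():
        return float(frame[int(round(r)), int(round(c))])
    return float(frame[r0:r1, c0:c1][disc].mean())


def log_response(frame: np.ndarray, diameter_um: float, pixel_size_um: float) -> np.ndarray:
    """Scale-normalized, sign-inverted LoG response tuned to the blob diameter."""
    sigma_px = (diameter_um / pixel_size_um) / (2.0 * np.sqrt(2.0))
    return -(sigma_px ** 2) * gaussian_laplace(np.asarray(frame, dtype=float), sigma_px)


def auto_log_threshold(responses: np.ndarray, noise_floor_sigmas: float = 5.0) -> float:
    """Otsu's threshold on pooled LoG responses, guarded by a robust noise floor.

    On data with no real blobs Otsu merely bisects the noise histogram; the
    floor (`noise_floor_sigmas` times the MAD-estimated response sd) keeps
    noise maxima from being promoted to detections in that case.
    """
    responses = np.asarray(responses, dtype=float).ravel()
    med = np.median(responses)
    robust_sd = 1.4826 * float(np.median(np.abs(responses - med)))
    return max(float(threshold_otsu(responses)), noise_floor_sigmas * robust_sd)


def detect_log(frame: np.ndarray, diameter_um: float = 8.0,
               threshold: float | str = "auto", pixel_size_um: float = 1.62,
               noise_floor_sigmas: float = 5.0) -> list[Spot]:
    """Laplacian-of-Gaussian blob detection with subpixel localization.

    The filter scale sigma = diameter / (2 sqrt 2) makes the (scale-normalized,
    sign-inverted) LoG respond maximally to bright blobs of the given
    diameter. Local maxima above the threshold become spots. The "auto"
    threshold is Otsu's on the response, guarded by a robust noise floor
    (`noise_floor_sigmas` times the MAD-estimated response sd): on a channel
    with no real blobs Otsu merely bisects the noise histogram, and without
    the floor it would promote noise maxima to detections.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    frame = np.asarray(frame, dtype=float)
    sigma_px = (diameter_um / pixel_size_um) / (2.0 * np.sqrt(2.0))
    response = log_response(frame, diameter_um, pixel_size_um)
    if isinstance(threshold, str):
        if response.max() <= response.min():
            return []
        threshold = auto_log_threshold(response, noise_floor_sigmas)
    peaks = peak_local_max(response, min_distance=max(1, int(round(sigma_px))),
                           threshold_abs=threshold, exclude_border=False)
    radius_px = (diameter_um / 2.0) / pixel_size_um
    spots = []
    for r, c in peaks:
        dr, dc = _quadratic_subpixel(response, r, c)
        spots.append(Spot(frame=0,
                          x_um=float(px_to_um(c + dc, pixel_size_um)),
                          y_um=float(px_to_um(r + dr, pixel_size_um)),
                          quality=float(response[r, c]),
                          intensity_mean=_spot_intensity(frame, r, c, radius_px)))
    return spots


def detect_threshold(frame: np.ndarray, threshold: float | str = "auto",
                     diameter_um: float = 8.0, pixel_size_um: float = 1.62) -> list[Spot]:
    """Threshold + connected components; spot = intensity-weighted centroid.

    The threshold is Otsu's when "auto". Components smaller than a quarter-
    diameter disc, pi (d/4)^2 px, are discarded as noise. Touching cells merge
    into one component and yield one spot (documented limitation).
    """
    frame = np.asarray(frame, dtype=float)
    if isinstance(threshold, str):
        if frame.max() <= frame.min():
            return []
        threshold = float(threshold_otsu(frame))
    binary = frame > threshold
    labels, n = label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    min_area = np.pi * ((diameter_um / pixel_size_um) / 4.0) ** 2
    areas = sum_labels(binary, labels, index=np.arange(1, n + 1))
    radius_px = (diameter_um / 2.0) / pixel_size_um
    spots = []
    yy, xx = np.mgrid[0:frame.shape[0], 0:frame.shape[1]]
    for i in np.flatnonzero(areas >= min_area) + 1:
        comp = labels == i
        weights = frame[comp]
        wsum = weights.sum()
        if wsum <= 0:
            continue
        r = float((yy[comp] * weights).sum() / wsum)
        c = float((xx[comp] * weights).sum() / wsum)
        spots.append(Spot(frame=0,
                          x_um=float(px_to_um(c, pixel_size_um)),
                          y_um=float(px_to_um(r, pixel_size_um)),
                          quality=float(weights.mean()),
                          intensity_mean=_spot_intensity(frame, r, c, radius_px)))
    return spots


def link(spots_by_frame, cfg: TrackerConfig) -> list[Track]:
    """Frame-to-frame LAP linking: Hungarian assignment on squared distance.

    Only pairs closer than the gate distance may link; unmatched detections
    start new tracks; with gap size 0 a track ends the first frame it finds
    no continuation. Deterministic and independent of spot input order up to
    track id numbering.
    """
    cfg.validate()
    gate2 = cfg.max_link_distance_um ** 2
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for frame_idx, spots in enumerate(spots_by_frame):
        spots = list(spots)
        assigned = [False] * len(spots)
        if active and spots:
            prev = np.array([[tr.spots[-1].x_um, tr.spots[-1].y_um] for tr in active])
            cur = np.array([[s.x_um, s.y_um] for s in spots])
            d2 = ((prev[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= gate2, d2, _GATE_COST)
            rows, cols = linear_sum_assignment(cost)
            still_active = set()
            for i, j in zip(rows, cols):
                if d2[i, j] <= gate2:
                    spot = spots[j]
                    spot.frame = frame_idx
                    active[i].append(spot)
                    assigned[j] = True
                    still_active.add(i)
            active = [tr for i, tr in enumerate(active) if i in still_active]
        else:
            active = []
        for j, spot in enumerate(spots):
            if not assigned[j]:
                spot.frame = frame_idx
                tr = Track(id=next_id, spots=[spot])
                next_id += 1
                tracks.append(tr)
                active.append(tr)
    return tracks


def filter_tracks(tracks: list[Track], cfg: TrackerConfig, frame_interval_s: float) -> list[Track]:
    """Drop tracks shorter than the minimum duration (kept when exactly equal)."""
    return [tr for tr in tracks if tr.duration_s(frame_interval_s) >= cfg.min_track_duration_s]


def _in_roi(spot: Spot, roi) -> bool:
    x0, y0, x1, y1 = roi
    return x0 <= spot.x_um <= x1 and y0 <= spot.y_um <= y1


def _working_frame(stack: ImageStack, t: int, cfg: TrackerConfig) -> np.ndarray:
    frame = stack.data[t].astype(float)
    if cfg.background_subtraction:
        frame = subtract_background(frame, cfg.rolling_ball_radius_um, stack.pixel_size_um)
    return frame


def resolve_auto_threshold(stack: ImageStack, cfg: TrackerConfig) -> float:
    """Resolve an "auto" detection threshold ONCE for a whole video.

    Interactive trackers set a single threshold per movie, not per frame;
    deriving it from a pooled frame subsample keeps detection stable over
    time (per-frame auto-thresholding flickers, and with gap size 0 every
    one-frame dropout splits a track). Pooled Otsu with the noise-floor guard
    for the LoG route; pooled Otsu of the intensities for the threshold route.
    """
    if not isinstance(cfg.detection_threshold, str):
        return float(cfg.detection_threshold)
    step = max(1, stack.n_frames // 12)
    sample = [_working_frame(stack, t, cfg) for t in range(0, stack.n_frames, step)]
    if cfg.detector == "log":
        pooled = np.stack([log_response(fr, cfg.spot_diameter_um, stack.pixel_size_um)
                           for fr in sample])
        if pooled.max() <= pooled.min():
            return np.inf
        return auto_log_threshold(pooled, cfg.noise_floor_sigmas)
    pooled = np.stack(sample)
    if pooled.max() <= pooled.min():
        return np.inf
    return float(threshold_otsu(pooled))


def detect_stack(stack: ImageStack, cfg: TrackerConfig) -> list[list[Spot]]:
    """Detect spots on every frame with one video-level threshold."""
    cfg.validate()
    threshold = resolve_auto_threshold(stack, cfg)
    spots_by_frame = []
    for t in range(stack.n_frames):
        work = _working_frame(stack, t, cfg)
        if cfg.detector == "log":
            spots = detect_log(work, cfg.spot_diameter_um, threshold,
                               stack.pixel_size_um, cfg.noise_floor_sigmas)
        else:
            spots = detect_threshold(work, threshold, cfg.spot_diameter_um,
                                     stack.pixel_size_um)
        if cfg.roi_um is not None:
            spots = [s for s in spots if _in_roi(s, cfg.roi_um)]
        for s in spots:
            s.frame = t
        spots_by_frame.append(spots)
    return spots_by_frame


def track_channel(stack: ImageStack, cfg: TrackerConfig) -> list[Track]:
    """Full per-channel pipeline: background subtraction, detection, linking,
    duration filtering. The same config is applicable to TL, fluorescence and
    pseudofluorescence channels for a fair comparison."""
    tracks = link(detect_stack(stack, cfg), cfg)
    return filter_tracks(tracks, cfg, stack.frame_interval_s)
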