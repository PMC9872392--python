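"""Image-stack and track-table I/O.

An ImageStack is the carrier between all pipeline stages: a T x Y x X
grayscale movie plus physical calibration. Stacks persist as multi-page TIFF,
tracks as a TrackMate-like CSV (track_id, frame, t_s, x_um, y_um, quality,
intensity_mean).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracks import Spot, Track

_TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "quality", "intensity_mean"]


@dataclass
class ImageStack:
    """T x Y x X grayscale movie with physical calibration."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_name: str = ""
    bit_depth: int = 8

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be T x Y x X, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("stack dimensions must all be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        """Total video duration (time from first to last frame start plus one interval)."""
        return self.n_frames * self.frame_interval_s

    @property
    def field_extent_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        h, w = self.frame_shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    def with_data(self, data: np.ndarray, channel_name: str | None = None) -> "ImageStack":
        return replace(self, data=data,
                       channel_name=self.channel_name if channel_name is None else channel_name)


def quantize(frame: np.ndarray, bit_depth: int, probability: bool) -> np.ndarray:
    """Float frame -> unsigned int codes; probability maps send 1.0 to the max code.

    Rounding is half-up (0.5 at 8-bit -> code 128).
    """
    max_code = 2 ** bit_depth - 1
    scaled = frame * max_code if probability else frame
    codes = np.floor(np.clip(scaled, 0, max_code) + 0.5)
    return codes.astype(np.uint8 if bit_depth == 8 else np.uint16)


def read_stack(path: str | Path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None, channel_name: str = "") -> ImageStack:
    """Read a grayscale multi-page TIFF; explicit calibration wins over TIFF tags."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if getattr(page, "samplesperpixel", 1) != 1:
            raise ValueError(f"{path}: only single-channel grayscale pages are supported "
                             f"(got {page.samplesperpixel} samples/pixel)")
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(page)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout {data.shape}: "
                         "only single-channel grayscale pages are supported")
    px = pixel_size_um if pixel_size_um is not None else tag_px
    if px is None:
        raise ValueError("pixel size not given and not present in TIFF tags")
    if frame_interval_s is None:
        raise ValueError("frame_interval_s is required (TIFF carries no time base)")
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return ImageStack(data, px, frame_interval_s, channel_name, bit_depth)


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except (KeyError, AttributeError):
        return None
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if not num:
        return None
    per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", unit) if unit else 1)
    if unit_um is None:
        return None
    return unit_um / per_unit


def write_stack(stack: ImageStack, path: str | Path, probability: bool | None = None) -> None:
    """Write a multi-page TIFF, one page per frame, at the stack's bit depth.

    Float data are quantized; `probability=None` auto-detects probability maps
    (float data with max <= 1) and scales them so 1.0 maps to the max code.
    """
    data = stack.data
    if np.issubdtype(data.dtype, np.floating):
        if probability is None:
            probability = float(np.nanmax(data, initial=0.0)) <= 1.0
        data = quantize(data, stack.bit_depth, probability)
    res = 10000.0 / stack.pixel_size_um  # pixels per centimeter
    tifffile.imwrite(path, data, photometric="minisblack",
                     resolution=(res, res), resolutionunit="CENTIMETER",
                     metadata={"channel": stack.channel_name,
                               "frame_interval_s": stack.frame_interval_s})


def write_tracks(tracks: list[Track], path: str | Path, frame_interval_s: float) -> None:
    rows = [
        (tr.id, s.frame, s.frame * frame_interval_s, s.x_um, s.y_um, s.quality, s.intensity_mean)
        for tr in tracks
        for s in tr.spots
    ]
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_tracks(path: str | Path) -> list[Track]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tracks: dict[int, Track] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            tid = int(row.track_id)
            spot = Spot(frame=int(row.frame), x_um=float(row.x_um), y_um=float(row.y_um),
                        quality=float(row.quality), intensity_mean=float(row.intensity_mean))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from None
        tr = tracks.setdefault(tid, Track(id=tid))
        try:
            tr.append(spot)
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return [tracks[k] for k in sorted(tracks)]
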