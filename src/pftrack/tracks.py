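"""Spot and Track containers shared by the simulator, tracker and metrics.

Coordinates are physical (µm) with the pixel-center convention: pixel index i
sits at (i + 0.5) * pixel_size µm. Frames are 0-based integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Spot:
    frame: int
    x_um: float
    y_um: float
    quality: float = 0.0
    intensity_mean: float = 0.0

    def position(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um])


@dataclass
class Track:
    id: int
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self):
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.id}: frames must be strictly increasing")

    def append(self, spot: Spot) -> None:
        if self.spots and spot.frame <= self.spots[-1].frame:
            raise ValueError(f"track {self.id}: frames must be strictly increasing")
        self.spots.append(spot)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def first_frame(self) -> int:
        return self.spots[0].frame

    @property
    def last_frame(self) -> int:
        return self.spots[-1].frame

    def duration_s(self, frame_interval_s: float) -> float:
        return (self.last_frame - self.first_frame) * frame_interval_s

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x_um, y_um)."""
        return np.array([[s.x_um, s.y_um] for s in self.spots])


def spots_by_frame(tracks: list[Track]) -> dict[int, list[tuple[int, Spot]]]:
    """Map frame -> list of (track_id, spot) over all tracks."""
    out: dict[int, list[tuple[int, Spot]]] = {}
    for tr in tracks:
        for s in tr.spots:
            out.setdefault(s.frame, []).append((tr.id, s))
    return out


def px_to_um(index: np.ndarray | float, pixel_size_um: float) -> np.ndarray | float:
    """Pixel index -> physical coordinate (pixel-center convention)."""
    return (np.asarray(index) + 0.5) * pixel_size_um


def um_to_px(coord: np.ndarray | float, pixel_size_um: float) -> np.ndarray | float:
    """Physical coordinate (µm) -> fractional pixel index."""
    return np.asarray(coord) / pixel_size_um - 0.5
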