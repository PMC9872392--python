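import numpy as np
import pytest

from pftrack.simulate import SceneConfig, simulate_scene, render_tl
from pftrack.tracks import Spot, Track


@pytest.fixture(scope="session")
def small_scene():
    """A small, fast scene shared by read-only tests."""
    cfg = SceneConfig(field_size_px=(128, 128), n_frames=10, n_cells=5, seed=42,
                      bleach_tau_s=600.0)
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def small_tl(small_scene):
    return render_tl(small_scene)


def make_track(track_id, frames, xs, ys):
    return Track(id=track_id, spots=[
        Spot(frame=f, x_um=float(x), y_um=float(y)) for f, x, y in zip(frames, xs, ys)])


def gaussian_blob(shape, cy, cx, sigma_px, amplitude=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px ** 2))
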