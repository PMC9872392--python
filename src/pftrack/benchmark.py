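"""The end-to-end synthetic validation experiment, at desk scale.

One committed recipe, shared by the test suite, the acceptance script and the
`eval` pipeline stage: simulate a benchmark scene (256 x 256 px at 1.62 µm/px,
90 frames at 20 s = 30 min, 15 round cells, bleaching fluorescence channel
with tau such that the fluorescence halves by the video end), train the
reduced patch classifier (depth 3, 8 base filters, 112 px input, 10 epochs,
600 augmented pairs from 30 crops of an independently seeded training scene),
convert the transmitted-light video to pseudofluorescence, track TL /
fluorescence / pseudofluorescence with one identical tracker config, and
measure detection rates, CLEAR-MOT scores, track durations, intensity decay
and SNR against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics
from .imgio import ImageStack
from .nn.train import TrainConfig, train
from .nn.unet import UNet, UNetConfig
from .simulate import (SceneConfig, SyntheticScene, export_training_pairs,
                       render_fluorescence, render_tl, simulate_scene)
from .tiling import convert_stack
from .tracking import TrackerConfig, detect_stack, track_channel
from .tracks import spots_by_frame

#: 30-minute video; tau = duration / ln 2 puts the fluorescence half-life
#: exactly at the video end.
BENCHMARK_DURATION_S = 90 * 20.0
BENCHMARK_BLEACH_TAU_S = float(BENCHMARK_DURATION_S / np.log(2.0))


def benchmark_scene_config(seed: int) -> SceneConfig:
    return SceneConfig(seed=seed, bleach_tau_s=BENCHMARK_BLEACH_TAU_S)


def benchmark_unet_config(seed: int) -> UNetConfig:
    return UNetConfig(depth=3, base_filters=8, input_px=112, seed=seed)


def benchmark_train_config(seed: int) -> TrainConfig:
    return TrainConfig(epochs=10, augmented_total=600, seed=seed)


def train_benchmark_model(seed: int, n_pairs: int = 30, max_restarts: int = 2) -> UNet:
    """Train the reduced classifier on crops from an independently seeded scene.

    At this training budget an occasional unlucky draw (initialization +
    augmentation stream) yields a model that fires on background texture. A
    quality gate catches such draws using the TRAINING scene only: a few
    frames are converted and spot-detected against that scene's own ground
    truth, and a catastrophic false-positive fraction triggers a restart with
    the next derived seed (the per-attempt seeds are deterministic, so the
    whole procedure remains a pure function of `seed`). Healthy draws sit at
    a few percent false positives, failed draws far above the 20% gate.
    """
    train_scene = simulate_scene(benchmark_scene_config(seed))
    pairs = export_training_pairs(train_scene, n_pairs, seed=seed + 1)
    tl = render_tl(train_scene)
    model = None
    for attempt in range(max_restarts + 1):
        attempt_seed = seed + 101 * attempt
        model = UNet(benchmark_unet_config(attempt_seed))
        train(model, pairs, benchmark_train_config(attempt_seed))
        if _training_scene_fp_fraction(model, train_scene, tl) <= 0.20:
            break
    return model


def _training_scene_fp_fraction(model: UNet, scene: SyntheticScene, tl: ImageStack,
                                frames: tuple[int, ...] = (0, 30, 60)) -> float:
    """Fraction of detections on a training-scene subsample that match no cell."""
    sub = ImageStack(tl.data[list(frames)], tl.pixel_size_um, tl.frame_interval_s, "TL",
                     tl.bit_depth)
    pf = convert_stack(sub, model, stride_px=42)
    spots = detect_stack(pf, TrackerConfig())
    gt_frames = spots_by_frame(scene.truth_tracks)
    per = [metrics.match_detections([s for _, s in gt_frames.get(f, [])], spots[i], 8.0)
           for i, f in enumerate(frames)]
    agg = metrics.aggregate_detections(per)
    return agg.fpr


@dataclass
class ChannelResult:
    name: str
    stack: ImageStack
    tracks: list
    duration_stats: metrics.TrackDurationSummary


@dataclass
class BenchmarkResult:
    scene: SyntheticScene
    channels: dict[str, ChannelResult]
    detection: metrics.DetectionMatchResult       # PF channel, per-frame aggregate
    mot: metrics.MotaResult                       # PF tracks vs truth
    match_radius_um: float
    snr_tl: float
    snr_pf: float
    snr_fluo: float
    pf_decay: np.ndarray                          # r(t) on the PF channel
    fluo_decay: np.ndarray

    @property
    def motp_score(self) -> float:
        return self.mot.motp_score(self.match_radius_um)


def run_benchmark(scene_seed: int, model: UNet | None = None, train_seed: int | None = None,
                  match_radius_um: float = 8.0) -> BenchmarkResult:
    """Run the full validation experiment for one test-scene seed.

    The model is trained once (on a scene seeded independently of any test
    scene) and may be shared across test seeds, mirroring the train-once /
    apply-to-many-videos workflow.
    """
    if model is None:
        model = train_benchmark_model(1000 + (train_seed if train_seed is not None else 0))

    config = benchmark_scene_config(scene_seed)
    scene = simulate_scene(config)
    tl = render_tl(scene)
    fluo = render_fluorescence(scene)
    # overlapping tiles with Hann blending: disjoint tiles dim cells that
    # straddle a seam (each tile normalizes independently), and with gap-0
    # linking every such one-frame dropout splits a track; a quarter-window
    # overlap (stride 42) gives every seam-adjacent cell an interior view in
    # the neighboring tile at half the cost of half-window overlap
    pf = convert_stack(tl, model, stride_px=42)

    tracker = TrackerConfig()
    channels = {}
    for name, stack in (("TL", tl), ("fluorescence", fluo), ("pseudofluorescence", pf)):
        tracks = track_channel(stack, tracker)
        stats = metrics.track_duration_stats(tracks, stack.duration_s, stack.frame_interval_s)
        channels[name] = ChannelResult(name, stack, tracks, stats)

    # detection rates on the PF channel, aggregated over frames
    gt_frames = spots_by_frame(scene.truth_tracks)
    per_frame = []
    pf_spots = detect_stack(pf, tracker)
    for t in range(pf.n_frames):
        gt = [s for _, s in gt_frames.get(t, [])]
        per_frame.append(metrics.match_detections(gt, pf_spots[t], match_radius_um))
    detection = metrics.aggregate_detections(per_frame)

    mot = metrics.mota_motp(scene.truth_tracks, channels["pseudofluorescence"].tracks,
                            match_radius_um)

    fg, bg = metrics.foreground_background_masks(scene.truth_masks[0], config.pixel_size_um,
                                                 clearance_um=tracker.spot_diameter_um)
    snr_tl = metrics.snr(tl.data[0], fg, bg).snr
    snr_pf = metrics.snr(pf.data[0], fg, bg).snr
    snr_fluo = metrics.snr(fluo.data[0], fg, bg).snr

    pf_decay = metrics.intensity_decay(pf, scene.label_masks)
    fluo_decay = metrics.intensity_decay(fluo, scene.label_masks)

    return BenchmarkResult(scene=scene, channels=channels, detection=detection, mot=mot,
                           match_radius_um=match_radius_um, snr_tl=snr_tl, snr_pf=snr_pf,
                           snr_fluo=snr_fluo, pf_decay=pf_decay, fluo_decay=fluo_decay)


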