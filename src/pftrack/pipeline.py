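"""Staged pipeline (simulate -> train -> convert -> track -> eval) over files.

Each stage reads its inputs from and writes its artifacts to one working
directory, records a manifest (inputs, outputs, config hash, seed), and fails
with an actionable error naming the stage that produces a missing upstream
artifact. All randomness flows from the seeds in the configuration, so a run
is reproducible from its config file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import typing
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import metrics
from .imgio import ImageStack, read_stack, read_tracks, write_stack, write_tracks
from .nn.train import TrainConfig, train
from .nn.unet import UNet, UNetConfig
from .simulate import (SceneConfig, export_training_pairs, mask_stack,
                       render_fluorescence, render_tl, simulate_scene)
from .tiling import convert_stack
from .tracking import TrackerConfig, track_channel
from .tracks import spots_by_frame

log = logging.getLogger("pftrack")

STAGES = ("simulate", "train", "convert", "track", "eval")

_FILES = {
    "tl": "tl.tif",
    "fluorescence": "fluorescence.tif",
    "masks": "masks.tif",
    "labels": "labels.tif",
    "truth": "truth_tracks.csv",
    "weights": "weights.npz",
    "pf": "pf.tif",
}


@dataclass
class TilingParams:
    window_px: int = 56
    upscale_factor: int = 4
    stride_px: int | None = None
    pad_mode: str = "reflect"


@dataclass
class EvalParams:
    match_radius_um: float = 8.0


@dataclass
class TrainingDataParams:
    n_pairs: int = 30
    crop_px: int = 56
    scene_seed: int | None = None  # default: scene.seed + 1000 (independent scene)


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tiling: TilingParams = field(default_factory=TilingParams)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    eval: EvalParams = field(default_factory=EvalParams)
    training_data: TrainingDataParams = field(default_factory=TrainingDataParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _build(cls, data):
    """Recursively construct a dataclass from plain dict/list data."""
    if not dataclasses.is_dataclass(cls):
        return data
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        ftype = hints.get(f.name, f.type)
        origin = typing.get_origin(ftype)
        if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
            value = _build(ftype, value)
        elif origin is tuple and isinstance(value, (list, tuple)):
            value = tuple(value)
        elif isinstance(value, list):
            value = tuple(value) if isinstance(getattr(cls, f.name, None), tuple) else value
        kwargs[f.name] = value
    return cls(**kwargs)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run stage '{producer}' first (or provide it)")
    return path


def _manifest(out_dir: Path, stage: str, cfg: RunConfig, inputs, outputs) -> None:
    payload = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.scene.seed,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / f"stage_{stage}.json").write_text(json.dumps(payload, indent=2))


def stage_simulate(cfg: RunConfig, out_dir: Path) -> None:
    scene = simulate_scene(cfg.scene)
    tl = render_tl(scene)
    write_stack(tl, out_dir / _FILES["tl"])
    outputs = [out_dir / _FILES["tl"], out_dir / _FILES["masks"],
               out_dir / _FILES["labels"], out_dir / _FILES["truth"]]
    write_stack(mask_stack(scene), out_dir / _FILES["masks"], probability=True)
    labels = ImageStack(scene.label_masks.astype(np.uint16), cfg.scene.pixel_size_um,
                        cfg.scene.frame_interval_s, "labels", 16)
    write_stack(labels, out_dir / _FILES["labels"], probability=False)
    write_tracks(scene.truth_tracks, out_dir / _FILES["truth"], cfg.scene.frame_interval_s)
    if cfg.scene.bleach_tau_s is not None:
        fluo = render_fluorescence(scene)
        write_stack(fluo, out_dir / _FILES["fluorescence"])
        outputs.append(out_dir / _FILES["fluorescence"])
    log.info("simulate: %d frames, %d cells -> %s", cfg.scene.n_frames, cfg.scene.n_cells, out_dir)
    _manifest(out_dir, "simulate", cfg, [], outputs)


def stage_train(cfg: RunConfig, out_dir: Path) -> None:
    td = cfg.training_data
    seed = td.scene_seed if td.scene_seed is not None else cfg.scene.seed + 1000
    train_scene = simulate_scene(dataclasses.replace(cfg.scene, seed=seed))
    pairs = export_training_pairs(train_scene, td.n_pairs, td.crop_px, seed=seed + 1)
    model = UNet(cfg.unet)
    history = train(model, pairs, cfg.train)
    weights = out_dir / _FILES["weights"]
    model.save_weights(weights, extra_meta={"train": dataclasses.asdict(cfg.train),
                                            "training_scene_seed": seed})
    (out_dir / "training_history.json").write_text(json.dumps(history, indent=2))
    log.info("train: final loss %.4f -> %s", history["loss"][-1], weights)
    _manifest(out_dir, "train", cfg, [], [weights])


def stage_convert(cfg: RunConfig, out_dir: Path) -> None:
    tl_path = _require(out_dir / _FILES["tl"], "simulate")
    weights = _require(out_dir / _FILES["weights"], "train")
    tl = read_stack(tl_path, cfg.scene.pixel_size_um, cfg.scene.frame_interval_s, "TL")
    model = UNet.load_weights(weights)
    pf = convert_stack(tl, model, cfg.tiling.window_px, cfg.tiling.upscale_factor,
                       cfg.tiling.stride_px, cfg.tiling.pad_mode)
    write_stack(pf, out_dir / _FILES["pf"], probability=True)
    log.info("convert: %s -> %s", tl_path.name, _FILES["pf"])
    _manifest(out_dir, "convert", cfg, [tl_path, weights], [out_dir / _FILES["pf"]])


def _channel_paths(out_dir: Path):
    return {"TL": out_dir / _FILES["tl"],
            "fluorescence": out_dir / _FILES["fluorescence"],
            "pseudofluorescence": out_dir / _FILES["pf"]}


def stage_track(cfg: RunConfig, out_dir: Path) -> None:
    _require(out_dir / _FILES["tl"], "simulate")
    inputs, outputs = [], []
    for name, path in _channel_paths(out_dir).items():
        if not path.exists():
            if name == "pseudofluorescence":
                _require(path, "convert")
            continue  # fluorescence is optional
        stack = read_stack(path, cfg.scene.pixel_size_um, cfg.scene.frame_interval_s, name)
        if name == "pseudofluorescence":
            stack = stack.with_data(stack.data.astype(np.float32) /
                                    (2 ** stack.bit_depth - 1))
        tracks = track_channel(stack, cfg.tracker)
        out = out_dir / f"tracks_{name}.csv"
        write_tracks(tracks, out, cfg.scene.frame_interval_s)
        log.info("track[%s]: %d tracks", name, len(tracks))
        inputs.append(path)
        outputs.append(out)
    _manifest(out_dir, "track", cfg, inputs, outputs)


def stage_eval(cfg: RunConfig, out_dir: Path) -> None:
    from .tracking import detect_stack

    truth_path = _require(out_dir / _FILES["truth"], "simulate")
    pf_path = _require(out_dir / _FILES["pf"], "convert")
    labels_path = _require(out_dir / _FILES["labels"], "simulate")
    masks_path = _require(out_dir / _FILES["masks"], "simulate")
    gt_tracks = read_tracks(truth_path)
    pf = read_stack(pf_path, cfg.scene.pixel_size_um, cfg.scene.frame_interval_s,
                    "pseudofluorescence")
    pf = pf.with_data(pf.data.astype(np.float32) / (2 ** pf.bit_depth - 1))
    labels = read_stack(labels_path, cfg.scene.pixel_size_um, cfg.scene.frame_interval_s).data
    masks = read_stack(masks_path, cfg.scene.pixel_size_um, cfg.scene.frame_interval_s).data > 0

    radius = cfg.eval.match_radius_um
    gt_frames = spots_by_frame(gt_tracks)
    det = detect_stack(pf, cfg.tracker)
    per_frame = [metrics.match_detections([s for _, s in gt_frames.get(t, [])], det[t], radius)
                 for t in range(pf.n_frames)]
    detection = metrics.aggregate_detections(per_frame)

    summary: dict = {
        "detection": {"tp": detection.tp, "fp": detection.fp, "fn": detection.fn,
                      "tpr": detection.tpr, "fpr": detection.fpr, "fnr": detection.fnr},
        "snr": {}, "track_duration_s": {}, "track_duration_percent": {},
    }
    inputs = [truth_path, pf_path, labels_path, masks_path]

    tracks_by_channel = {}
    for name, _ in _channel_paths(out_dir).items():
        tpath = out_dir / f"tracks_{name}.csv"
        if tpath.exists():
            tracks_by_channel[name] = read_tracks(tpath)
            inputs.append(tpath)
    if "pseudofluorescence" in tracks_by_channel:
        mot = metrics.mota_motp(gt_tracks, tracks_by_channel["pseudofluorescence"], radius)
        summary["mota"] = {"mota": mot.mota, "motp_score": mot.motp_score(radius),
                           "motp_mean_distance_um": mot.motp_mean_distance_um,
                           "misses": mot.misses, "false_positives": mot.false_positives,
                           "id_switches": mot.id_switches, "gt_count": mot.gt_count}
    video_s = pf.duration_s
    for name, tracks in tracks_by_channel.items():
        stats = metrics.track_duration_stats(tracks, video_s, cfg.scene.frame_interval_s)
        summary["track_duration_s"][name] = stats.mean_s
        summary["track_duration_percent"][name] = stats.mean_percent

    fg, bg = metrics.foreground_background_masks(masks[0], cfg.scene.pixel_size_um,
                                                 cfg.tracker.spot_diameter_um)
    for name, path in _channel_paths(out_dir).items():
        if path.exists():
            stack = read_stack(path, cfg.scene.pixel_size_um, cfg.scene.frame_interval_s)
            summary["snr"][name] = metrics.snr(stack.data[0], fg, bg).snr
    summary["pf_intensity_decay_min"] = float(np.min(metrics.intensity_decay(pf, labels)))

    out = out_dir / "summary.json"
    out.write_text(json.dumps(summary, indent=2))
    log.info("eval: summary -> %s", out)
    _manifest(out_dir, "eval", cfg, inputs, [out])


_STAGE_FN = {
    "simulate": stage_simulate,
    "train": stage_train,
    "convert": stage_convert,
    "track": stage_track,
    "eval": stage_eval,
}


def run_pipeline(cfg: RunConfig, stages, out_dir: str | Path) -> Path:
    """Run the requested stages in canonical order; returns the output directory."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            log.info("--- stage %s ---", stage)
            _STAGE_FN[stage](cfg, out_dir)
    return out_dir
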