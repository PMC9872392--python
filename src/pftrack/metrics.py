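"""Quantitative validation measures: SNR, photobleaching decay, track-duration
statistics, detection matching (TPR/FPR/FNR), CLEAR-MOT accuracy/precision,
the intensity-shift robustness benchmark, and the in-cell probability decay
profile.

Conventions fixed here (and used consistently by the acceptance experiments):
SNR = (mean FG - mean BG) / std BG with the population standard deviation;
detection and MOT matching use one-to-one optimal assignment under a distance
gate whose default radius equals the spot diameter (8 µm); the MOT precision
is reported both as the raw mean matched distance and as the bounded score
motp_score = 1 - mean distance / radius (higher is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.optimize import linear_sum_assignment
from scipy.stats import mannwhitneyu, spearmanr

from .imgio import ImageStack
from .tracks import Spot, Track, spots_by_frame

_GATE_COST = 1e12


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------

@dataclass
class SNRResult:
    snr: float
    fg_mean: float
    bg_mean: float
    bg_std: float
    n_fg: int
    n_bg: int


def snr(frame: np.ndarray, fg_mask: np.ndarray, bg_mask: np.ndarray) -> SNRResult:
    """(mean FG - mean BG) / std BG, population std; constant background is an error."""
    fg_mask = np.asarray(fg_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if (fg_mask & bg_mask).any():
        raise ValueError("foreground and background masks overlap")
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("foreground and background masks must both be non-empty")
    frame = np.asarray(frame, dtype=float)
    fg = frame[fg_mask]
    bg = frame[bg_mask]
    bg_std = float(bg.std())  # population std
    if bg_std == 0:
        raise ValueError("background is constant: SNR undefined")
    return SNRResult(snr=float((fg.mean() - bg.mean()) / bg_std),
                     fg_mean=float(fg.mean()), bg_mean=float(bg.mean()),
                     bg_std=bg_std, n_fg=int(fg.size), n_bg=int(bg.size))


def foreground_background_masks(truth_mask: np.ndarray, pixel_size_um: float,
                                clearance_um: float = 8.0):
    """FG = cell pixels; BG = pixels farther than `clearance_um` (one spot
    diameter by default) from any cell."""
    truth_mask = np.asarray(truth_mask, dtype=bool)
    dist_um = distance_transform_edt(~truth_mask) * pixel_size_um
    return truth_mask, dist_um > clearance_um


# --------------------------------------------------------------------------
# photobleaching / intensity decay
# --------------------------------------------------------------------------

def intensity_decay(stack: ImageStack, label_masks: np.ndarray) -> np.ndarray:
    """r(t) = mean over cells of (mean in-cell intensity at t) / (same at t = 0).

    `label_masks` is a (T, Y, X) integer array, 0 = background, cell id + 1
    inside each cell. Cells absent from a frame are skipped at that t;
    r(0) = 1 by construction.
    """
    if stack.data.shape != label_masks.shape:
        raise ValueError("stack and label masks differ in shape")
    ids = np.unique(label_masks)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no labeled cell regions")
    t_total = stack.n_frames
    means = np.full((t_total, ids.size), np.nan)
    for t in range(t_total):
        frame = stack.data[t].astype(float)
        lab = label_masks[t]
        for k, cid in enumerate(ids):
            sel = lab == cid
            if sel.any():
                means[t, k] = frame[sel].mean()
    base = means[0]
    valid = ~np.isnan(base) & (base != 0)
    if not valid.any():
        raise ValueError("zero or missing initial in-cell intensity")
    ratios = means[:, valid] / base[valid]
    return np.nanmean(ratios, axis=1)


# --------------------------------------------------------------------------
# track durations
# --------------------------------------------------------------------------

@dataclass
class TrackDurationSummary:
    durations_s: np.ndarray
    percent_of_video: np.ndarray
    mean_s: float
    median_s: float
    mean_percent: float
    n_tracks: int


def track_duration_stats(tracks: list[Track], video_duration_s: float,
                         frame_interval_s: float) -> TrackDurationSummary:
    """Per-track durations in seconds and as % of the video duration."""
    if video_duration_s <= 0:
        raise ValueError("video duration must be positive")
    durations = np.array([tr.duration_s(frame_interval_s) for tr in tracks], dtype=float)
    percent = 100.0 * durations / video_duration_s
    if durations.size == 0:
        return TrackDurationSummary(durations, percent, 0.0, 0.0, 0.0, 0)
    return TrackDurationSummary(durations, percent, float(durations.mean()),
                                float(np.median(durations)), float(percent.mean()),
                                int(durations.size))


def mann_whitney(x, y, alternative: str = "two-sided"):
    """Two-sample Mann-Whitney U comparison; returns (U, p).

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's "auto" policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# detection matching
# --------------------------------------------------------------------------

@dataclass
class DetectionMatchResult:
    tp: int
    fp: int
    fn: int
    match_radius_um: float

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fnr(self) -> float:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def _positions(spots: list[Spot]) -> np.ndarray:
    return np.array([[s.x_um, s.y_um] for s in spots]).reshape(-1, 2)


def match_positions(gt: np.ndarray, det: np.ndarray, radius_um: float):
    """Optimal one-to-one matching under a distance gate.

    Returns (pairs, dists): index pairs (i_gt, j_det) and their distances.
    """
    if len(gt) == 0 or len(det) == 0:
        return [], []
    d = np.linalg.norm(gt[:, None, :] - det[None, :, :], axis=2)
    cost = np.where(d <= radius_um, d ** 2, _GATE_COST)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= radius_um]
    dists = [float(d[i, j]) for i, j in pairs]
    return pairs, dists


def match_detections(gt_spots: list[Spot], det_spots: list[Spot],
                     radius_um: float = 8.0) -> DetectionMatchResult:
    """One frame's detections vs ground truth; unmatched gt -> FN, unmatched det -> FP."""
    pairs, _ = match_positions(_positions(gt_spots), _positions(det_spots), radius_um)
    tp = len(pairs)
    return DetectionMatchResult(tp=tp, fp=len(det_spots) - tp, fn=len(gt_spots) - tp,
                                match_radius_um=radius_um)


def aggregate_detections(results: list[DetectionMatchResult]) -> DetectionMatchResult:
    """Pool per-frame counts into one aggregate rate set."""
    if not results:
        raise ValueError("nothing to aggregate")
    radius = results[0].match_radius_um
    return DetectionMatchResult(tp=sum(r.tp for r in results), fp=sum(r.fp for r in results),
                                fn=sum(r.fn for r in results), match_radius_um=radius)


# --------------------------------------------------------------------------
# CLEAR-MOT
# --------------------------------------------------------------------------

@dataclass
class MotaResult:
    misses: int
    false_positives: int
    id_switches: int
    gt_count: int
    matched_distances: list[float] = field(default_factory=list)

    @property
    def mota(self) -> float:
        return 1.0 - (self.misses + self.false_positives + self.id_switches) / self.gt_count

    @property
    def motp_mean_distance_um(self) -> float:
        return float(np.mean(self.matched_distances)) if self.matched_distances else np.nan

    def motp_score(self, radius_um: float) -> float:
        """1 - mean matched distance / radius, in [0, 1]; higher is better."""
        if not self.matched_distances:
            return 0.0
        return float(np.clip(1.0 - self.motp_mean_distance_um / radius_um, 0.0, 1.0))


def mota_motp(gt_tracks: list[Track], est_tracks: list[Track],
              radius_um: float = 8.0) -> MotaResult:
    """CLEAR-MOT evaluation with identity-continuity matching.

    Frame by frame: matches from the previous frame are kept while the pair
    stays within the gate; remaining objects are matched optimally; a ground
    truth re-matched to a different estimate than before counts one identity
    switch. Misses are unmatched ground-truth spots, false positives unmatched
    estimates.
    """
    gt_by_frame = spots_by_frame(gt_tracks)
    est_by_frame = spots_by_frame(est_tracks)
    if not gt_by_frame:
        raise ValueError("no ground-truth spots")
    frames = sorted(set(gt_by_frame) | set(est_by_frame))
    misses = fps = switches = gt_count = 0
    dists: list[float] = []
    mapping: dict[int, int] = {}       # gt track id -> est track id
    last_match: dict[int, int] = {}    # gt track id -> last matched est id ever
    for f in frames:
        gts = gt_by_frame.get(f, [])
        ests = est_by_frame.get(f, [])
        gt_count += len(gts)
        gt_ids = [tid for tid, _ in gts]
        est_ids = [tid for tid, _ in ests]
        gt_pos = _positions([s for _, s in gts])
        est_pos = _positions([s for _, s in ests])
        matched_gt: dict[int, int] = {}
        # keep surviving correspondences
        for gi, gid in enumerate(gt_ids):
            eid = mapping.get(gid)
            if eid is not None and eid in est_ids:
                ej = est_ids.index(eid)
                dist = float(np.linalg.norm(gt_pos[gi] - est_pos[ej]))
                if dist <= radius_um:
                    matched_gt[gi] = ej
                    dists.append(dist)
        free_g = [i for i in range(len(gts)) if i not in matched_gt]
        used_e = set(matched_gt.values())
        free_e = [j for j in range(len(ests)) if j not in used_e]
        if free_g and free_e:
            pairs, pair_d = match_positions(gt_pos[free_g], est_pos[free_e], radius_um)
            for (a, b), dist in zip(pairs, pair_d):
                gi, ej = free_g[a], free_e[b]
                matched_gt[gi] = ej
                dists.append(dist)
        new_mapping: dict[int, int] = {}
        for gi, ej in matched_gt.items():
            gid, eid = gt_ids[gi], est_ids[ej]
            if gid in last_match and last_match[gid] != eid:
                switches += 1
            new_mapping[gid] = eid
            last_match[gid] = eid
        misses += len(gts) - len(matched_gt)
        fps += len(ests) - len(matched_gt)
        mapping = new_mapping
    return MotaResult(misses=misses, false_positives=fps, id_switches=switches,
                      gt_count=gt_count, matched_distances=dists)


# --------------------------------------------------------------------------
# intensity-shift robustness benchmark
# --------------------------------------------------------------------------

def intensity_shift_benchmark(model, pairs, shifts, max_code: int = 255) -> pd.DataFrame:
    """Segmentation robustness to additive intensity offsets.

    For each shift s: add s (in code units) to the TL crop, clip at the bit
    depth maximum, predict, threshold at 0.5; report IoU against the truth
    mask and the mean absolute difference between the probability map and the
    mask. Returns a DataFrame with columns shift, iou, pixel_difference.
    """
    from .nn.unet import predict_window

    rows = []
    for s in shifts:
        inter = union = 0
        diffs = []
        for pair in pairs:
            img = np.clip(pair.image * max_code + s, 0, max_code) / max_code
            prob = predict_window(model, img.astype(np.float32))
            pred = prob >= 0.5
            truth = pair.mask > 0
            inter += int((pred & truth).sum())
            union += int((pred | truth).sum())
            diffs.append(np.abs(prob - truth.astype(float)).mean())
        rows.append((float(s), inter / union if union else 1.0, float(np.mean(diffs))))
    return pd.DataFrame(rows, columns=["shift", "iou", "pixel_difference"])


# --------------------------------------------------------------------------
# probability decay toward cell borders
# --------------------------------------------------------------------------

@dataclass
class BorderDecayProfile:
    distance_px: np.ndarray   # signed distance bin centers (>0 inside cells)
    mean_probability: np.ndarray
    spearman_inside: float    # correlation of depth vs probability inside cells


def border_decay_profile(prob_map: np.ndarray, truth_mask: np.ndarray,
                         max_depth_px: int = 10) -> BorderDecayProfile:
    """Mean class-1 probability binned by signed distance to the cell border.

    Positive distances are inside cells; a positive Spearman correlation of
    in-cell depth vs probability means the map peaks inside objects and decays
    toward their borders.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if not truth_mask.any():
        raise ValueError("empty truth mask")
    prob_map = np.asarray(prob_map, dtype=float)
    inside = distance_transform_edt(truth_mask)
    outside = distance_transform_edt(~truth_mask)
    signed = np.where(truth_mask, inside, -outside)
    bins = np.arange(-max_depth_px, max_depth_px + 1)
    centers, means = [], []
    for b in bins:
        sel = np.round(signed) == b
        if sel.any():
            centers.append(float(b))
            means.append(float(prob_map[sel].mean()))
    depth = signed[truth_mask]
    prob_in = prob_map[truth_mask]
    if np.unique(depth).size > 1 and np.unique(prob_in).size > 1:
        rho = float(spearmanr(depth, prob_in).statistic)
    else:
        rho = 0.0
    return BorderDecayProfile(np.array(centers), np.array(means), rho)
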