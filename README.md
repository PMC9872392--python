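# pftrack — label-free cell tracking via U-Net pseudofluorescence

Long time-lapse imaging of cells migrating in wide 3-D chambers is usually
done in transmitted light (TL): fluorescent labels bleach and are phototoxic
over hours-long acquisitions, and the large fields of view force low
magnification, leaving each cell only a handful of pixels with intensity close
to the background. Standard spot detectors and trackers fail on such data.

`pftrack` converts a TL movie into a **pseudofluorescence** channel: every
56 × 56 px window is upscaled 4×, classified by a small U-Net, and the
per-pixel class-1 (cell) probability is stitched back into a full-frame image.
On that channel, ordinary blob detection and nearest-frame linking work the
way they do on a real fluorescence stain — without the bleaching. The package
is aimed at microscopists and image-analysis developers who want a fully
scriptable, dependency-light reimplementation of this workflow, plus the means
to validate every stage without real data.

## What is inside

- `pftrack.simulate` — a seeded synthetic wide-chamber microscopy generator:
  persistent-random-walk cells (~8 µm at 1.62 µm/px), zero-net-flux
  dark-core/bright-rim TL profiles, defocus blur along a z random walk,
  illumination gradient, shot + read noise, an exponentially bleaching
  fluorescence channel, and exact ground-truth masks and tracks.
- `pftrack.nn` — the U-Net patch classifier (numpy + numba, no deep-learning
  framework required), with the published training recipe: Adam, lr 1e-4,
  batch 2, binary cross-entropy, rotation/zoom/shift/shear/flip augmentation,
  112 px training resolution.
- `pftrack.tiling` — windowing, 4× upscaling, probability downscaling and
  seamless reassembly.
- `pftrack.tracking` — LoG and threshold spot detection (8 µm default
  diameter, automatic thresholding), Hungarian frame-to-frame linking gated at
  20 µm with gap size 0, and the 300 s minimum-duration filter.
- `pftrack.metrics` — SNR, photobleaching decay curves, track-duration
  statistics, detection matching (TPR/FPR/FNR), CLEAR-MOT (MOTA + MOTP
  score), intensity-shift robustness, border-decay profiles, Mann-Whitney U.
- `pftrack.pipeline` / the `pftrack` CLI — the staged workflow
  `simulate → train → convert → track → eval` over TIFF/CSV/YAML files.

The model at the core: a frame is tiled into windows *W*; each window is
min-max normalized and upscaled; the U-Net *f* yields class-1 probabilities
p(x) = f(W)(x) ∈ [0, 1]; the stitched map P replaces the fluorescence channel.
Spots are LoG maxima of P at σ = d/(2√2) (d = 8 µm); links minimize
Σ‖x_t − x_{t+1}‖² under ‖·‖ ≤ 20 µm; MOTP score = 1 − (mean matched
distance)/r at r = 8 µm.

## Worked example

```python
from pftrack.benchmark import run_benchmark, train_benchmark_model

model = train_benchmark_model(seed=1001)   # ~5 min on one CPU core
result = run_benchmark(scene_seed=1, model=model)

d = result.detection
print(f"detection: TPR {100*d.tpr:.1f}%  FNR {100*d.fnr:.1f}%  FPR {100*d.fpr:.1f}%")
print(f"MOTP score {result.motp_score:.3f}")
print(f"track duration  TL {result.channels['TL'].duration_stats.mean_s:.0f} s"
      f"  PF {result.channels['pseudofluorescence'].duration_stats.mean_s:.0f} s")
print(f"PF intensity floor {100*result.pf_decay.min():.1f}%"
      f"  fluorescence floor {100*result.fluo_decay.min():.1f}%")
print(f"SNR  TL {result.snr_tl:.1f}  PF {result.snr_pf:.1f}")
```

This trains the reduced classifier on 30 crops from a synthetic training
scene, converts an independent 90-frame test video (256 × 256 px, 15 cells,
20 s interval) to pseudofluorescence, tracks TL, fluorescence and
pseudofluorescence with one identical tracker configuration, and prints
(exact values vary slightly per seed):

```
detection: TPR 98.7%  FNR 1.3%  FPR 4.7%
MOTP score 0.968
track duration  TL 432 s  PF 1640 s
PF intensity floor 97.3%  fluorescence floor 56.5%
SNR  TL -2.1  PF 728.4
```

Read: on the pseudofluorescence channel nearly every cell is detected with
few spurious spots; automatic tracks last ~3.8× longer than on raw TL; the
pseudofluorescence signal does not bleach (stays above 80% of its initial
value) while the real fluorescence channel decays to ~57%; and the channel's
SNR jumps from about zero — cells are no brighter than the TL background —
to far above real fluorescence, because the probability map's background is
nearly noise-free.

The same pipeline is available from the shell:

```bash
pftrack run --config examples/benchmark.yaml --seed 1 --out run/
pftrack convert --in tl.tif --weights run/weights.npz --pixel-size 1.62 --interval 20 --out out/
```

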