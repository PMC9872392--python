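scene:
  field_size_px:
  - 256
  - 256
  pixel_size_um: 1.62
  frame_interval_s: 20.0
  n_frames: 90
  n_cells: 15
  cell_diameter_um_mean: 8.0
  cell_diameter_um_sd: 0.5
  morphology: round
  motility:
    speed_um_per_s_mean: 0.08
    speed_um_per_s_sd: 0.03
    persistence: 0.7
    drift_um_per_frame:
    - 0.0
    - 0.0
  focus:
    z_range_um: 12.0
    blur_sigma_um_per_um: 0.1
    z_step_fraction: 0.125
  illumination:
    gradient_amplitude: 0.1
  noise:
    gaussian_sd: 1.5
    poisson_scale: 0.15
  bleach_tau_s: 2596.8510736001344
  contrast: 1.0
  tl_intensity_jitter_sd: 0.1
  background_level: 100.0
  fluorescence_amplitude: 120.0
  fluorescence_background: 10.0
  bit_depth: 8
  seed: 1
unet:
  depth: 3
  base_filters: 8
  input_px: 112
  kernel: 3
  in_channels: 1
  norm_span_floor: 0.25
  seed: 1
train:
  learning_rate: 0.0001
  batch_size: 2
  epochs: 10
  augmented_total: 600
  aug:
    rotation_range: 0.5
    rotation_unit: deg
    zoom_range: 0.5
    shift_range: 0.5
    shear_range: 0.2
    hflip: true
    vflip: true
  val_fraction: 0.1
  seed: 1
tiling:
  window_px: 56
  upscale_factor: 4
  stride_px: 42
  pad_mode: reflect
tracker:
  spot_diameter_um: 8.0
  max_link_distance_um: 20.0
  max_gap_frames: 0
  min_track_duration_s: 300.0
  detector: log
  detection_threshold: auto
  noise_floor_sigmas: 5.0
  background_subtraction: false
  rolling_ball_radius_um: 16.0
  roi_um: null
eval:
  match_radius_um: 8.0
training_data:
  n_pairs: 30
  crop_px: 56
  scene_seed: null
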