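import dataclasses

import numpy as np
import pytest

from pftrack import metrics
from pftrack.simulate import (FocusModel, IlluminationModel, MotilityModel, NoiseModel,
                              SceneConfig, export_training_pairs, read_training_pairs,
                              render_fluorescence, render_tl, simulate_scene,
                              write_training_pairs)
from pftrack.tracks import um_to_px


def quiet_noise():
    return NoiseModel(gaussian_sd=0.0, poisson_scale=0.0)


class TestSimulateScene:
    def test_empty_scene(self):
        scene = simulate_scene(SceneConfig(field_size_px=(40, 40), n_frames=3, n_cells=0))
        assert scene.truth_masks.sum() == 0
        assert scene.truth_tracks == []

    def test_single_frame_tracks(self):
        scene = simulate_scene(SceneConfig(field_size_px=(64, 64), n_frames=1, n_cells=3))
        assert len(scene.truth_tracks) == 3
        assert all(tr.n_spots == 1 for tr in scene.truth_tracks)

    def test_pure_drift_is_straight_line(self):
        cfg = SceneConfig(
            field_size_px=(64, 64), n_frames=10, n_cells=2, seed=3,
            motility=MotilityModel(speed_um_per_s_mean=0.1, speed_um_per_s_sd=0.0,
                                   persistence=1.0, drift_um_per_frame=(1.0, 0.0)))
        scene = simulate_scene(cfg)
        for tr in scene.truth_tracks:
            steps = np.diff(tr.positions(), axis=0)
            np.testing.assert_allclose(steps[:, 0], 1.0, atol=1e-9)
            np.testing.assert_allclose(steps[:, 1], 0.0, atol=1e-9)

    def test_displacement_bound(self):
        mot = MotilityModel(speed_um_per_s_mean=0.1, speed_um_per_s_sd=0.05,
                            persistence=0.5)
        cfg = SceneConfig(field_size_px=(200, 200), n_frames=40, n_cells=10,
                          motility=mot, seed=4)
        scene = simulate_scene(cfg)
        bound = (mot.speed_um_per_s_mean + 4 * mot.speed_um_per_s_sd) * cfg.frame_interval_s
        for tr in scene.truth_tracks:
            steps = np.linalg.norm(np.diff(tr.positions(), axis=0), axis=1)
            assert (steps <= bound + 1e-6).all()

    def test_centroids_inside_field(self):
        cfg = SceneConfig(field_size_px=(80, 120), n_frames=60, n_cells=8, seed=5,
                          motility=MotilityModel(speed_um_per_s_mean=0.3,
                                                 speed_um_per_s_sd=0.1, persistence=0.9))
        scene = simulate_scene(cfg)
        w_um, h_um = cfg.field_extent_um
        pos = scene.positions_um
        assert (pos[..., 0] >= 0).all() and (pos[..., 0] <= w_um).all()
        assert (pos[..., 1] >= 0).all() and (pos[..., 1] <= h_um).all()

    def test_mask_centroid_matches_track_position(self):
        cfg = SceneConfig(field_size_px=(128, 128), n_frames=5, n_cells=4, seed=6)
        scene = simulate_scene(cfg)
        for t in range(cfg.n_frames):
            for c in range(scene.n_cells):
                sel = scene.label_masks[t] == c + 1
                if sel.sum() < 5:
                    continue
                ys, xs = np.nonzero(sel)
                cx, cy = um_to_px(scene.positions_um[t, c], cfg.pixel_size_um)
                assert abs(xs.mean() - cx) <= 2.0
                assert abs(ys.mean() - cy) <= 2.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate_scene(SceneConfig(pixel_size_um=-1))
        with pytest.raises(ValueError):
            simulate_scene(SceneConfig(n_frames=0))
        with pytest.raises(ValueError):
            simulate_scene(SceneConfig(morphology="square"))


class TestDeterminism:
    def test_bit_identical_renders(self):
        cfg = SceneConfig(field_size_px=(64, 64), n_frames=4, n_cells=5, seed=7,
                          bleach_tau_s=500.0)
        a, b = simulate_scene(cfg), simulate_scene(cfg)
        np.testing.assert_array_equal(a.positions_um, b.positions_um)
        np.testing.assert_array_equal(render_tl(a).data, render_tl(b).data)
        np.testing.assert_array_equal(render_fluorescence(a).data,
                                      render_fluorescence(b).data)

    def test_earlier_frames_stable_under_longer_video(self):
        base = SceneConfig(field_size_px=(64, 64), n_frames=4, n_cells=5, seed=8)
        longer = dataclasses.replace(base, n_frames=8)
        a, b = simulate_scene(base), simulate_scene(longer)
        np.testing.assert_array_equal(a.positions_um, b.positions_um[:4])
        np.testing.assert_array_equal(render_tl(a).data, render_tl(b).data[:4])


class TestRenderTL:
    def test_flat_background_without_cells_noise_gradient(self):
        cfg = SceneConfig(field_size_px=(32, 32), n_frames=2, n_cells=0,
                          noise=quiet_noise(), illumination=IlluminationModel(0.0))
        tl = render_tl(simulate_scene(cfg))
        np.testing.assert_allclose(tl.data, cfg.background_level)

    def test_zero_contrast_hides_cells(self):
        cfg = SceneConfig(field_size_px=(64, 64), n_frames=2, n_cells=6, contrast=0.0,
                          noise=quiet_noise(), illumination=IlluminationModel(0.0), seed=9)
        tl = render_tl(simulate_scene(cfg))
        np.testing.assert_allclose(tl.data, cfg.background_level, atol=1e-5)

    def test_defocus_reduces_in_cell_variance(self):
        cfg = SceneConfig(field_size_px=(64, 64), n_frames=1, n_cells=1,
                          noise=quiet_noise(), seed=10,
                          focus=FocusModel(z_range_um=20.0, blur_sigma_um_per_um=0.3))
        scene = simulate_scene(cfg)
        scene.z_offsets_um[:] = 0.0
        sharp = render_tl(scene).data[0]
        scene.z_offsets_um[:] = 10.0
        blurred = render_tl(scene).data[0]
        mask = scene.truth_masks[0] > 0
        assert blurred[mask].var() < sharp[mask].var()

    def test_low_snr_by_construction(self):
        cfg = SceneConfig(field_size_px=(128, 128), n_frames=1, n_cells=6, seed=11)
        scene = simulate_scene(cfg)
        tl = render_tl(scene)
        fg, bg = metrics.foreground_background_masks(scene.truth_masks[0], cfg.pixel_size_um)
        # cells are never brighter than background in TL: the ring profile has
        # (near-)zero net flux, so the mask-mean SNR stays at or below zero
        assert metrics.snr(tl.data[0], fg, bg).snr < 1.0


class TestRenderFluorescence:
    def _cfg(self, **kw):
        # stationary cells: in-cell means are then driven by bleaching alone,
        # not by sub-pixel re-rasterization of the moving mask
        base = dict(field_size_px=(64, 64), n_frames=6, n_cells=3, seed=12,
                    noise=quiet_noise(), bleach_tau_s=600.0,
                    motility=MotilityModel(speed_um_per_s_mean=0.0, speed_um_per_s_sd=0.0),
                    focus=FocusModel(z_range_um=0.0, blur_sigma_um_per_um=0.0))
        base.update(kw)
        return SceneConfig(**base)

    def test_requires_bleach_tau(self):
        scene = simulate_scene(self._cfg(bleach_tau_s=None))
        with pytest.raises(ValueError, match="bleach_tau_s"):
            render_fluorescence(scene)

    def test_no_decay_with_huge_tau(self):
        scene = simulate_scene(self._cfg(bleach_tau_s=1e12))
        fluo = render_fluorescence(scene)
        r = metrics.intensity_decay(fluo, scene.label_masks)
        np.testing.assert_allclose(r, 1.0, atol=1e-3)

    def test_half_life(self):
        # tau such that the last frame sits exactly at one half-life; zero
        # fluorescence background so the in-cell mean is pure cell signal
        # (the background is unbleached and would otherwise bias the ratio up)
        cfg = self._cfg(n_frames=11)
        tau = 10 * cfg.frame_interval_s / np.log(2.0)
        scene = simulate_scene(self._cfg(n_frames=11, bleach_tau_s=tau,
                                         fluorescence_background=0.0))
        fluo = render_fluorescence(scene)
        r = metrics.intensity_decay(fluo, scene.label_masks)
        assert r[0] == pytest.approx(1.0)
        assert r[-1] == pytest.approx(0.5, abs=0.02)

    def test_snr_ordering_tl_below_fluorescence(self):
        cfg = SceneConfig(field_size_px=(128, 128), n_frames=1, n_cells=6, seed=13,
                          bleach_tau_s=600.0)
        scene = simulate_scene(cfg)
        fg, bg = metrics.foreground_background_masks(scene.truth_masks[0], cfg.pixel_size_um)
        snr_tl = metrics.snr(render_tl(scene).data[0], fg, bg).snr
        snr_fl = metrics.snr(render_fluorescence(scene).data[0], fg, bg).snr
        assert snr_tl < snr_fl


class TestTrainingPairExport:
    def test_crop_physical_size(self):
        cfg = SceneConfig()
        assert 56 * cfg.pixel_size_um == pytest.approx(90.72)  # the "91 µm" crop

    def test_deterministic_export(self, small_scene, small_tl):
        a = export_training_pairs(small_scene, 3, seed=14, tl=small_tl)
        b = export_training_pairs(small_scene, 3, seed=14, tl=small_tl)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image, pb.image)
            np.testing.assert_array_equal(pa.mask, pb.mask)

    def test_background_scene_gives_empty_masks(self):
        cfg = SceneConfig(field_size_px=(64, 64), n_frames=2, n_cells=0)
        pairs = export_training_pairs(simulate_scene(cfg), 4, seed=15)
        assert all(p.mask.sum() == 0 for p in pairs)

    def test_invalid_args_rejected(self, small_scene, small_tl):
        with pytest.raises(ValueError):
            export_training_pairs(small_scene, 0, tl=small_tl)
        with pytest.raises(ValueError):
            export_training_pairs(small_scene, 1, crop_px=500, tl=small_tl)

    def test_png_round_trip(self, small_scene, small_tl, tmp_path):
        pairs = export_training_pairs(small_scene, 3, seed=16, tl=small_tl)
        write_training_pairs(pairs, tmp_path)
        back = read_training_pairs(tmp_path)
        assert len(back) == 3
        for orig, rt in zip(pairs, back):
            np.testing.assert_array_equal(rt.mask, orig.mask)
            np.testing.assert_allclose(rt.image, orig.image, atol=1 / 255)
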