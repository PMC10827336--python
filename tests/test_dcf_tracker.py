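"""Correlation-filter tracking: detection, recovery, failure modes."""

import numpy as np
import pytest
from scipy import ndimage

import speckletrack as st
from speckletrack.dcf_tracker import (
    TrackerConfig,
    _channel_responses,
    _windowed_features,
    spatial_reliability_mask,
)
from speckletrack.roi_geometry import BoundingBox

BBOX = BoundingBox(80, 80, 40, 40)  # around the blob at (100, 100)


def center_error(center, truth):
    return float(np.hypot(center[0] - truth[0], center[1] - truth[1]))


class TestInitTracker:
    def test_self_detection_under_one_pixel(self, textured_image):
        state = st.init_tracker(textured_image, BBOX)
        _, res = st.track_step(state, textured_image)
        assert center_error(res.center, (100, 100)) < 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.init_tracker(np.full((100, 100), 3.0), BoundingBox(30, 30, 20, 20))

    def test_bbox_outside_image_rejected(self, textured_image):
        with pytest.raises(ValueError):
            st.init_tracker(textured_image, BoundingBox(500, 500, 40, 40))

    def test_tiny_bbox_rejected(self, textured_image):
        with pytest.raises(ValueError):
            st.init_tracker(textured_image, BoundingBox(10, 10, 3, 3))

    def test_training_frame_peak_is_global_maximum(self, textured_image):
        # exhaustive scan: no location in the search window out-responds
        # the training center on the training frame itself
        state = st.init_tracker(textured_image, BBOX)
        chans = _windowed_features(
            textured_image, state.last_center, state.template_size, state.spatial_mask
        )
        resp = np.tensordot(
            state.channel_weights, _channel_responses(state, chans), axes=1
        )
        H, W = state.template_size
        py, px = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(py - (H - 1) / 2) <= 1 and abs(px - (W - 1) / 2) <= 1


class TestSpatialReliabilityMask:
    def test_bright_disc_mask_covers_disc_excludes_ring(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disc = ((xx - 40) ** 2 + (yy - 40) ** 2 <= 15**2).astype(float)
        patch = disc * 2.0 + 0.1
        bbox = BoundingBox(20, 20, 40, 40)
        mask = spatial_reliability_mask(patch, bbox)
        hard = mask > 0.5
        assert hard[disc.astype(bool)].mean() > 0.9  # covers the disc
        ring = ~disc.astype(bool)
        assert hard[ring].mean() < 0.1  # excludes >=90% of the background

    def test_uniform_patch_falls_back_to_bbox(self):
        mask = spatial_reliability_mask(np.ones((60, 60)), BoundingBox(15, 15, 30, 30))
        hard = mask > 0.5
        assert hard.sum() >= 0.8 * 30 * 30  # all-ones over the box (softened)

    def test_mask_never_exceeds_template(self, textured_image):
        patch = textured_image[60:140, 60:140]
        mask = spatial_reliability_mask(patch, BoundingBox(20, 20, 40, 40))
        assert mask.shape == patch.shape
        assert mask.max() <= 1.0 + 1e-9


class TestTrackStep:
    def test_recovers_translation(self, textured_image):
        state = st.init_tracker(textured_image, BBOX)
        shifted = ndimage.shift(textured_image, (3, 5), order=1, mode="reflect")
        _, res = st.track_step(state, shifted)
        assert center_error(res.center, (105, 103)) <= 1.0

    def test_static_noisy_sequence_drift_below_2px(self, textured_image):
        # 30 frames, additive noise at 20 dB SNR, zero true motion
        rng = np.random.default_rng(3)
        sigma = textured_image.std() / 10.0
        state = st.init_tracker(textured_image, BBOX)
        for _ in range(30):
            noisy = textured_image + rng.normal(0, sigma, textured_image.shape)
            state, res = st.track_step(state, noisy)
        assert center_error(res.center, (100, 100)) < 2.0

    def test_constant_velocity_2px_mean_error_below_2px(self, textured_image):
        state = st.init_tracker(textured_image, BBOX)
        errs = []
        for t in range(1, 51):
            frame = ndimage.shift(textured_image, (0, 2 * t), order=1, mode="reflect")
            state, res = st.track_step(state, frame)
            errs.append(center_error(res.center, (100 + 2 * t, 100)))
        assert np.mean(errs) <= 2.0

    def test_fast_motion_with_small_search_window_fails(self, textured_image):
        # 15 px/frame against a 10 px search radius: the tracker lags
        cfg = TrackerConfig(search_radius_px=10.0)
        state = st.init_tracker(textured_image, BBOX, cfg)
        for t in range(1, 6):
            frame = ndimage.shift(textured_image, (0, 15 * t), order=1, mode="reflect")
            state, res = st.track_step(state, frame)
        assert res.lost or center_error(res.center, (100 + 15 * 5, 100)) > 5.0

    def test_bbox_size_fixed_throughout(self, textured_image):
        state = st.init_tracker(textured_image, BBOX)
        for t in range(5):
            frame = ndimage.shift(textured_image, (t, t), order=1, mode="reflect")
            state, res = st.track_step(state, frame)
            assert (res.bbox.w, res.bbox.h) == (BBOX.w, BBOX.h)

    def test_translation_equivariance(self, textured_image):
        # tracking a globally shifted copy of a sequence yields the same
        # trajectory shifted by exactly the same offset
        def run(offset):
            img0 = ndimage.shift(
                textured_image, (offset[1], offset[0]), order=1, mode="reflect"
            )
            bb = BoundingBox(BBOX.x + offset[0], BBOX.y + offset[1], BBOX.w, BBOX.h)
            state = st.init_tracker(img0, bb)
            centers = []
            for t in range(1, 8):
                frame = ndimage.shift(
                    textured_image,
                    (offset[1] + t, offset[0] + 2 * t),
                    order=1,
                    mode="reflect",
                )
                state, res = st.track_step(state, frame)
                centers.append(res.center)
            return np.asarray(centers)

        a = run((0.0, 0.0))
        b = run((6.0, 4.0))
        np.testing.assert_allclose(b - a, np.broadcast_to([6.0, 4.0], a.shape), atol=0.35)

    def test_ground_truth_trajectories_on_simulated_sequences(self):
        # >= 5 seeded simulated sequences: mean per-frame center error < 3 px
        # against the simulator's recorded ground truth
        for seed in range(5):
            sim, run_cfg = st.slow_scenario(seed=seed, n_frames=15)
            seq = st.simulate_sequence(sim)
            track_img = lambda f: st.spatial_contrast(f, 7).k_values
            roi = sim.lesion_geometries[0]
            state = st.init_tracker(
                track_img(seq.frames[0]), st.circumscribed_bbox(roi), run_cfg.tracker
            )
            errs = []
            for t in range(1, len(seq.frames)):
                state, res = st.track_step(state, track_img(seq.frames[t]))
                errs.append(center_error(res.center, seq.truth_centers[t, 0]))
            assert np.mean(errs) < 3.0, f"seed {seed}: mean error {np.mean(errs)}"


class TestRoiUpdate:
    def test_subthreshold_displacement_keeps_roi(self):
        roi = st.CircleRoi(10, 10, 5)
        out, moved = st.roi_update(roi, (10, 10), (10.4, 10.3), threshold_px=1.0)
        assert out == roi and not moved

    def test_suprathreshold_displacement_moves_roi(self):
        roi = st.CircleRoi(10, 10, 5)
        out, moved = st.roi_update(roi, (10, 10), (15, 10), threshold_px=1.0)
        assert moved and (out.cx, out.cy) == (15, 10)

    def test_zero_threshold_moves_on_any_displacement(self):
        roi = st.CircleRoi(10, 10, 5)
        _, moved = st.roi_update(roi, (10, 10), (10.01, 10), threshold_px=0.0)
        assert moved

    def test_jitter_suppression_is_exact(self):
        # i.i.d. center noise below the threshold: the ROI never moves
        rng = np.random.default_rng(0)
        roi = st.CircleRoi(50, 50, 10)
        for _ in range(200):
            jitter = rng.uniform(-0.6, 0.6, 2)  # magnitude < 1 px threshold
            roi, moved = st.roi_update(
                roi, (50, 50), (50 + jitter[0], 50 + jitter[1]), threshold_px=1.0
            )
            assert not moved
        assert (roi.cx, roi.cy) == (50, 50)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            st.roi_update(st.CircleRoi(0, 0, 5), (0, 0), (1, 1), threshold_px=-1)
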