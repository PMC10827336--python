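"""Speckle contrast, flow index, rendering and background segmentation."""

import numpy as np
import pytest

import speckletrack as st
from speckletrack.speckle_core import RawFrame


def brute_force_contrast(pixels: np.ndarray, window: int) -> np.ndarray:
    """Independent oracle: per-pixel loop over symmetric-padded neighborhoods."""
    half = window // 2
    padded = np.pad(pixels, half, mode="symmetric")
    out = np.zeros_like(pixels, dtype=np.float64)
    for i in range(pixels.shape[0]):
        for j in range(pixels.shape[1]):
            win = padded[i : i + window, j : j + window]
            mu = win.mean()
            out[i, j] = 0.0 if mu == 0 else win.std() / mu
    return out


class TestSpatialContrast:
    def test_center_pixel_of_3x3_ramp(self):
        frame = np.arange(1.0, 10.0).reshape(3, 3)
        k = st.spatial_contrast(frame, 3).k_values
        # sigma = population std of 1..9 = 2.5820, mean = 5
        assert k[1, 1] == pytest.approx(np.std(frame) / 5.0, abs=1e-12)
        assert k[1, 1] == pytest.approx(0.5164, abs=1e-4)

    def test_constant_frame_has_zero_contrast(self):
        k = st.spatial_contrast(np.full((16, 16), 7.0), 5).k_values
        assert np.all(k == 0.0)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_brute_force_oracle(self, window, rng):
        pixels = rng.exponential(size=(64, 64))
        k = st.spatial_contrast(pixels, window).k_values
        np.testing.assert_allclose(k, brute_force_contrast(pixels, window), atol=1e-10)

    def test_zero_mean_windows_give_zero(self):
        pixels = np.zeros((12, 12))
        pixels[8:, 8:] = 3.0
        k = st.spatial_contrast(pixels, 3).k_values
        assert k[0, 0] == 0.0 and np.all(np.isfinite(k))

    @pytest.mark.parametrize("c", [0.25, 3.0, 1e4])
    def test_scale_invariance(self, c, rng):
        pixels = rng.exponential(size=(32, 32)) + 0.1
        k1 = st.spatial_contrast(pixels, 5).k_values
        k2 = st.spatial_contrast(c * pixels, 5).k_values
        np.testing.assert_allclose(k1, k2, rtol=1e-9)

    def test_output_shape_matches_input(self, rng):
        pixels = rng.exponential(size=(40, 56))
        assert st.spatial_contrast(pixels, 7).shape == (40, 56)

    @pytest.mark.parametrize("window", [2, 4, 1, 99])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            st.spatial_contrast(np.ones((8, 8)), window)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            RawFrame(np.zeros((0, 5)))


class TestTemporalContrast:
    def test_identical_frames_zero_contrast(self):
        cube = np.tile(np.random.default_rng(1).exponential(size=(8, 8)), (4, 1, 1))
        maps = st.temporal_contrast(cube, depth=4)
        assert len(maps) == 1
        assert np.all(maps[0].k_values == 0.0)

    def test_two_frame_pair(self):
        cube = np.stack([np.full((4, 4), 2.0), np.full((4, 4), 4.0)])
        k = st.temporal_contrast(cube, depth=2)[0].k_values
        np.testing.assert_allclose(k, 1.0 / 3.0)  # sigma=1, mean=3

    def test_window_count(self, rng):
        cube = rng.exponential(size=(10, 6, 6))
        assert len(st.temporal_contrast(cube, depth=4)) == 7

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            st.temporal_contrast(rng.exponential(size=(3, 6, 6)), depth=5)

    def test_ergodicity_temporal_matches_spatial(self):
        # stationary fully decorrelating speckle is ergodic: the mean
        # temporal K over a region matches the spatial sigma/mean contrast
        # of a single frame of that region to within sampling error
        rng = np.random.default_rng(5)
        frames = [
            np.abs(st.synth_speckle_field((96, 96), 0.5, seed=rng)) ** 2
            for _ in range(64)
        ]
        cube = np.stack(frames)
        kt = st.temporal_contrast(cube, depth=64)[0].k_values.mean()
        ks = np.mean([f.std() / f.mean() for f in frames[:8]])
        assert kt == pytest.approx(ks, rel=0.05)


class TestFlowIndex:
    def test_known_values(self):
        contrast = st.ContrastImage(np.array([[0.5, 1.0]]), 7, "spatial")
        np.testing.assert_allclose(st.flow_index(contrast).values, [[4.0, 1.0]])

    def test_zero_contrast_clamped(self):
        contrast = st.ContrastImage(np.array([[0.0]]), 7, "spatial")
        fi = st.flow_index(contrast, k_floor=1e-3)
        assert fi.values[0, 0] == pytest.approx(1e6)
        assert np.isfinite(fi.values).all()

    def test_monotone_decreasing_in_k(self, rng):
        k = np.sort(rng.uniform(0.01, 1.5, size=50))
        fi = st.flow_index(st.ContrastImage(k[None], 7, "spatial")).values[0]
        assert np.all(np.diff(fi) < 0)

    def test_invalid_floor_rejected(self):
        contrast = st.ContrastImage(np.array([[0.5]]), 7, "spatial")
        with pytest.raises(ValueError):
            st.flow_index(contrast, k_floor=0.0)


class TestRenderContrastMap:
    def test_endpoints_blue_to_red(self):
        # low K = high flow -> red channel dominates; high K = low flow -> blue
        k = np.array([[0.1, 1.0]])
        rgb = st.render_contrast_map(
            st.ContrastImage(k, 7, "spatial"), vmin=1.0, vmax=100.0
        )
        red_px, blue_px = rgb[0, 0], rgb[0, 1]
        assert red_px[0] > red_px[2]  # R > B at the high-flow end
        assert blue_px[2] > blue_px[0]  # B > R at the low-flow end

    def test_equal_values_equal_colors_and_determinism(self, rng):
        k = rng.uniform(0.2, 1.0, size=(8, 8))
        k[0, 0] = k[7, 7] = 0.5
        ci = st.ContrastImage(k, 7, "spatial")
        a = st.render_contrast_map(ci, 0.0, 30.0)
        b = st.render_contrast_map(ci, 0.0, 30.0)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a[0, 0], a[7, 7])

    def test_invalid_range_rejected(self):
        ci = st.ContrastImage(np.ones((4, 4)), 7, "spatial")
        with pytest.raises(ValueError):
            st.render_contrast_map(ci, vmin=2.0, vmax=1.0)


class TestSegmentBackground:
    def test_simulated_scene_separates_regions(self):
        # static dim background (K ~ 1) around fast tissue (K ~ 0.35)
        tissue = st.PolygonRoi(((20, 20), (140, 20), (140, 140), (20, 140)))
        cfg = st.SimulationConfig(
            shape=(160, 160),
            tissue_tau=0.1,
            tissue_region=tissue,
            n_frames=1,
            exposure_substeps=8,
            seed=11,
        )
        seq = st.simulate_sequence(cfg)
        contrast = st.spatial_contrast(seq.frames[0], 7)
        mask = st.segment_background(contrast, threshold=0.6)
        tissue_mask = st.roi_mask(tissue, (160, 160))
        # erode boundaries: the contrast window straddles the region edge
        from scipy import ndimage

        interior = ndimage.binary_erosion(tissue_mask, iterations=5)
        exterior = ndimage.binary_erosion(~tissue_mask, iterations=5)
        assert mask[exterior].mean() >= 0.95  # background flagged True
        assert (~mask)[interior].mean() >= 0.95  # tissue flagged False

    def test_threshold_extremes(self, rng):
        k = rng.uniform(0.1, 0.9, size=(8, 8))
        ci = st.ContrastImage(k, 7, "spatial")
        assert not st.segment_background(ci, threshold=1.5).any()
        assert st.segment_background(ci, threshold=0.0).all()
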