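"""Morphodynamic windowing, edge velocity, and coupling statistics."""

import numpy as np
import pytest
from scipy import ndimage

from tensionmap import segment, synth, windows


@pytest.fixture(scope="module")
def disk_series():
    masks, _ = synth.make_mask_series((128, 128), 6, 40)
    return masks


@pytest.fixture(scope="module")
def disk_grid(disk_series):
    return windows.build_window_grid(disk_series, window_px=5, n_bands=6)


class TestBuildWindowGrid:
    def test_position_count_from_perimeter(self, disk_grid):
        # circle of radius 40: perimeter ~ 2*pi*40 ~ 251 px -> ~50 windows
        # (the marching-squares contour of a rasterized disk runs a few
        # per cent longer than the ideal circle)
        assert abs(disk_grid.n_pos - round(2 * np.pi * 40 / 5)) <= 5

    def test_constant_position_count_across_frames(self, disk_grid):
        for t in range(disk_grid.n_frames):
            pos = disk_grid.pos_labels[t]
            assert pos.max() == disk_grid.n_pos - 1
            assert pos[disk_grid.band_labels[t] > 0].min() >= 0

    def test_bands_tile_the_edge_region_exactly(self, disk_series, disk_grid):
        m = disk_series[0]
        edt = ndimage.distance_transform_edt(m)
        for k in (1, 3, 6):
            union = (disk_grid.band_labels[0] >= 1) & (disk_grid.band_labels[0] <= k)
            assert np.array_equal(union, m & (edt <= 5 * k))

    def test_static_mask_gives_static_labels(self, disk_grid):
        assert np.array_equal(disk_grid.band_labels[0], disk_grid.band_labels[3])
        assert np.array_equal(disk_grid.pos_labels[0], disk_grid.pos_labels[3])

    def test_band_distance_geometry(self, disk_grid):
        # band 3 center: 2.5 windows * 5 px * 160 nm = 2.0 um from the edge
        assert disk_grid.band_distance_um(3) == pytest.approx(2.0)
        assert disk_grid.band_distance_um(1) == pytest.approx(0.4)

    def test_tiny_mask_raises(self):
        masks = np.zeros((1, 16, 16), bool)
        masks[0, 8, 8] = True
        with pytest.raises(ValueError, match="boundary shorter"):
            windows.build_window_grid(masks, window_px=50)


class TestWindowSignal:
    def test_constant_map_gives_constant_windows(self, disk_series, disk_grid):
        stack = np.where(disk_series, 3.25, np.nan)
        sig = windows.window_signal(stack.astype(float), disk_grid)
        assert sig.shape == (6, disk_grid.n_pos, 6)
        assert np.allclose(sig[np.isfinite(sig)], 3.25)

    def test_matches_per_window_oracle(self, disk_series, disk_grid, rng):
        stack = np.where(disk_series, rng.random(disk_series.shape), np.nan)
        sig = windows.window_signal(stack.astype(float), disk_grid)
        t = 2
        for band in (1, 4):
            for pos in (0, disk_grid.n_pos // 2):
                wm = disk_grid.window_mask(t, band, pos)
                vals = stack[t][wm]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    assert sig[band - 1, pos, t] == pytest.approx(vals.mean())
                else:
                    assert np.isnan(sig[band - 1, pos, t])

    def test_empty_windows_are_nan_not_zero(self, disk_series, disk_grid):
        stack = np.full(disk_series.shape, np.nan)
        sig = windows.window_signal(stack, disk_grid)
        assert np.isnan(sig).all()


class TestEdgeVelocity:
    def test_static_mask_zero_velocity(self, disk_series, disk_grid):
        v = windows.edge_velocity(disk_series, disk_grid)
        assert v.velocity_nm_s.shape == (disk_grid.n_pos, 5)
        # baseline subtraction makes static masks exactly zero
        assert np.nanmax(np.abs(v.velocity_nm_s)) == 0.0

    def test_uniform_expansion_measured_everywhere(self):
        masks = np.stack([
            synth._disk_mask((128, 128), (64, 64), 30 + 2 * t) for t in range(4)
        ])
        grid = windows.build_window_grid(masks, window_px=5, n_bands=3,
                                         frame_interval_s=5.0)
        v = windows.edge_velocity(masks, grid)
        # 2 px/frame * 160 nm / 5 s = 64 nm/s, protrusion positive
        assert np.nanmedian(v.velocity_nm_s) == pytest.approx(64.0, rel=0.15)
        assert np.all(v.velocity_nm_s[np.isfinite(v.velocity_nm_s)] > 0)


class TestTemporalCrosscorr:
    def test_planted_lag_detected(self, disk_grid, rng):
        T = 40
        a = rng.normal(0, 1, (disk_grid.n_bands, disk_grid.n_pos, T))
        b = np.roll(a, 2, axis=2)  # b delayed by 2 frames
        res = windows.temporal_crosscorr(a, b, disk_grid, max_lag=5,
                                         n_permutations=200, seed=1)
        assert len(res) == disk_grid.n_bands
        for bc in res:
            assert bc.peak_lag == 2
            assert bc.peak_correlation > 0.8
            assert bc.p_value < 0.05

    def test_independent_noise_is_null(self, disk_grid, rng):
        T = 40
        a = rng.normal(0, 1, (disk_grid.n_bands, disk_grid.n_pos, T))
        b = rng.normal(0, 1, (disk_grid.n_pos, T))  # 2-D broadcast form
        res = windows.temporal_crosscorr(a, b, disk_grid, max_lag=5,
                                         n_permutations=200, seed=2)
        # individual bands can produce chance p < 0.05; demand no
        # systematic coupling instead of per-band significance
        ps = [bc.p_value for bc in res]
        assert np.median(ps) > 0.1
        assert min(ps) > 0.001
        assert all(abs(bc.peak_correlation) < 0.2 for bc in res)

    def test_short_series_skipped(self, disk_grid, rng):
        a = rng.normal(0, 1, (disk_grid.n_bands, disk_grid.n_pos, 6))
        res = windows.temporal_crosscorr(a, a, disk_grid, min_frames=10)
        assert res == []


class TestSpatialLocalization:
    def test_signal_planted_in_band_three(self, disk_grid, rng):
        T = disk_grid.n_frames
        n_pos = disk_grid.n_pos
        protrusive = np.zeros((n_pos, T), bool)
        protrusive[: n_pos // 3] = True
        F = rng.normal(1.0, 0.05, (disk_grid.n_bands, n_pos, T))
        F[2, : n_pos // 3, :] += 1.0  # band 3 high exactly in protrusive sectors
        res = windows.spatial_localization_corr(F, protrusive, disk_grid,
                                                n_permutations=300, seed=3)
        best = max(res, key=lambda bc: bc.peak_correlation)
        assert best.band == 3
        assert best.distance_um == pytest.approx(2.0)
        assert best.p_value < 0.05

    def test_protrusive_positions_from_events(self):
        masks, truth = synth.make_mask_series(
            (160, 160), 8, 35, protrusions=[synth.ProtrusionSpec(2, 4, 1200)]
        )
        grid = windows.build_window_grid(masks, window_px=5, n_bands=4)
        events = segment.detect_protrusions(masks, min_volume=1000)
        ind = windows.protrusive_positions(grid, events)
        assert ind.shape == (grid.n_pos, 8)
        assert not ind[:, :2].any()  # nothing before onset
        assert ind[:, 2:6].any()
        # the marked sector is localized, not the whole boundary
        assert ind[:, 3].sum() < grid.n_pos // 2


class TestForceVelocityRegression:
    def test_recovers_planted_line(self, rng):
        x = rng.uniform(1, 5, 40)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.3, 40)
        out = windows.force_velocity_regression(x, y)
        assert out["slope"] == pytest.approx(2.0, rel=0.1)
        assert out["intercept"] == pytest.approx(1.0, abs=0.5)
        assert out["r"] > 0.9
        assert out["ci95"][0] < out["r"] < out["ci95"][1] or out["ci95"][0] <= out["r"]
        assert out["n"] == 40

    def test_ci_brackets_r(self, rng):
        x = rng.uniform(0, 1, 30)
        y = x + rng.normal(0, 0.5, 30)
        out = windows.force_velocity_regression(x, y)
        lo, hi = out["ci95"]
        assert lo < out["r"] < hi

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError, match=">= 3 events"):
            windows.force_velocity_regression([1, 2], [3, 4])


class TestLeadingEdgeForce:
    def test_mean_over_valid_pixels(self):
        stack = np.full((2, 8, 8), np.nan)
        stack[0, :2, :2] = 4.0
        regions = np.zeros((2, 8, 8), bool)
        regions[0, :4, :4] = True
        mean, n = windows.leading_edge_force(stack, regions)
        assert mean == 4.0 and n == 4

    def test_no_pixels_raises(self):
        stack = np.full((1, 4, 4), np.nan)
        with pytest.raises(ValueError, match="no valid leading-edge"):
            windows.leading_edge_force(stack, np.ones((1, 4, 4), bool))
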