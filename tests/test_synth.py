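"""Synthetic-scene generators: forward-model fidelity and determinism."""

import numpy as np
import pytest

from tensionmap import calibration as cal
from tensionmap import synth


def _clean_params(**kw):
    base = dict(
        n_frames=2, noise=False, bleach=False, shading=False,
        background_signal=0.0, force_field_spec=0.0,
    )
    base.update(kw)
    return synth.SceneParams(**base)


class TestCellScene:
    def test_noiseless_zero_force_ratio_is_uniform(self, model):
        sc = synth.make_cell_scene(_clean_params(), model)
        mask = sc.truth["mask_series"][0]
        d = sc.channels["donor"][0] - 100.0
        f = sc.channels["fret"][0] - 100.0
        ratio = f[mask] / d[mask]
        assert np.allclose(ratio, model.zero_force_ratio, atol=1e-9)

    def test_planted_ring_radiometry(self, model):
        """Mean rendered ratio inside a planted 3 pN ring matches the
        forward model within shot-noise error."""
        spec = [("ring", {"center": (64, 64), "r_in": 15, "r_out": 25}, 3.0)]
        p = synth.SceneParams(n_frames=1, force_field_spec=spec, bleach=False, seed=7)
        sc = synth.make_cell_scene(p, model)
        ring = synth._disk_mask((128, 128), (64, 64), 25) & ~synth._disk_mask(
            (128, 128), (64, 64), 15
        )
        d = sc.channels["donor"][0] / sc.truth["shading"] - p.dark_level
        f = sc.channels["fret"][0] / sc.truth["shading"] - p.dark_level
        measured = (f[ring].mean() - p.background_signal) / (
            d[ring].mean() - p.background_signal
        )
        expected = float(model.ratio_for_force(3.0))
        # Poisson error of the ring means, propagated to the ratio
        n = ring.sum()
        rel = np.sqrt(2.0 / (p.donor_level * n))
        assert measured == pytest.approx(expected, rel=5 * rel + 1e-3)

    def test_same_seed_bit_identical(self, model):
        p = synth.SceneParams(n_frames=3, seed=11, force_field_spec=1.0)
        a = synth.make_cell_scene(p, model)
        b = synth.make_cell_scene(p, model)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_out_of_domain_force_raises(self, model):
        with pytest.raises(ValueError, match="outside calibrated"):
            synth.make_cell_scene(_clean_params(force_field_spec=8.0), model)

    def test_bleaching_decays_fret_only(self, model):
        p = _clean_params(n_frames=10, bleach=True)
        p = p.replace(bleach_rate=0.05)
        sc = synth.make_cell_scene(p, model)
        mask = sc.truth["mask_series"][0]
        d0 = sc.channels["donor"][0][mask] - p.dark_level
        d9 = sc.channels["donor"][9][mask] - p.dark_level
        f0 = sc.channels["fret"][0][mask] - p.dark_level
        f9 = sc.channels["fret"][9][mask] - p.dark_level
        assert np.allclose(d0, d9)
        assert f9.mean() / f0.mean() == pytest.approx(np.exp(-0.05 * 9), rel=1e-6)

    def test_background_noise_matches_poisson_plus_read_model(self, model):
        """Sample variance in a uniform background region agrees with the
        planted Poisson + Gaussian-read noise model within 10%."""
        p = synth.SceneParams(
            n_frames=1, shading=False, background_signal=200.0, seed=3,
            cell_radius=20.0, shape=(256, 256),
        )
        sc = synth.make_cell_scene(p, model)
        bgreg = ~synth._disk_mask((256, 256), (128, 128), 40)
        v = sc.channels["donor"][0][bgreg].var()
        expected = 200.0 + p.read_noise_sd**2
        assert v == pytest.approx(expected, rel=0.10)


class TestMaskSeries:
    def test_planted_protrusion_volume_is_exact(self):
        masks, truth = synth.make_mask_series(
            (160, 160), 8, 35, protrusions=[synth.ProtrusionSpec(2, 4, 1200)]
        )
        gains = masks[1:] & ~masks[:-1]
        assert truth["events"][0]["volume"] == 1200
        assert int(gains.sum()) == 1200
        # gains confined to the scheduled frames
        per_frame = gains.reshape(gains.shape[0], -1).sum(axis=1)
        assert np.all(per_frame[: 1] == 0) and np.all(per_frame[5:] == 0)

    def test_oversized_protrusion_raises(self):
        with pytest.raises(ValueError, match="does not fit"):
            synth.make_mask_series(
                (64, 64), 6, 20, protrusions=[synth.ProtrusionSpec(1, 3, 5000)]
            )


class TestZStackScene:
    def test_zero_offset_profiles_peak_together(self):
        sc = synth.make_zstack_scene(0.0, step=25.0, noise=False)
        v1 = sc.channels["ch1"].var(axis=(1, 2)) / sc.channels["ch1"].mean(axis=(1, 2)) ** 2
        v2 = sc.channels["ch2"].var(axis=(1, 2)) / sc.channels["ch2"].mean(axis=(1, 2)) ** 2
        assert np.argmax(v1) == np.argmax(v2)

    def test_determinism(self):
        a = synth.make_zstack_scene(30.0, seed=5)
        b = synth.make_zstack_scene(30.0, seed=5)
        assert np.array_equal(a.channels["ch1"], b.channels["ch1"])

    def test_focus_near_edge_raises(self):
        with pytest.raises(ValueError, match="scan edge"):
            synth.make_zstack_scene(900.0, step=25.0, n_planes=21)


@pytest.fixture(scope="module")
def base(model):
    p = synth.SceneParams(
        n_frames=1, force_field_spec="random", cell_radius=58,
        shape=(140, 140), seed=21, bleach=False,
    )
    return synth.make_cell_scene(p, model)


class TestStainScene:
    def _measured_r(self, scene):
        mask = scene.truth["mask_series"][0]
        inv = -scene.truth["ratio_true"][mask]
        ab = scene.channels["antibody"][0][mask]
        return np.corrcoef(ab, inv)[0, 1]

    def test_rho_one_is_affine(self, base):
        sc = synth.make_stain_scene(base, rho=1.0)
        assert self._measured_r(sc) == pytest.approx(1.0, abs=1e-9)

    def test_rho_zero_within_null_band(self, base):
        sc = synth.make_stain_scene(base, rho=0.0, seed=2)
        n = int(base.truth["mask_series"][0].sum())
        assert abs(self._measured_r(sc)) <= 1.96 / np.sqrt(n - 3) + 1e-9

    def test_rho_negative_point_three(self, base):
        sc = synth.make_stain_scene(base, rho=-0.3, seed=3)
        n = int(base.truth["mask_series"][0].sum())
        assert n >= 10_000
        assert -0.4 <= self._measured_r(sc) <= -0.2
        assert sc.truth["stain_rho"] == -0.3

    def test_invalid_rho_raises(self, base):
        with pytest.raises(ValueError):
            synth.make_stain_scene(base, rho=1.5)


class TestCalibrationTable:
    def test_noiseless_refit_recovers_truth(self):
        points, truth = synth.make_calibration_table(13, noise_sd=0.0)
        curve = cal.fit_force_efficiency_curve(points)
        assert np.allclose(curve.coeffs, truth, rtol=1e-9, atol=1e-12)

    def test_noisy_fit_close_to_truth(self):
        """With 50 points at noise_sd 0.01 the refit curve typically lies
        within 0.02 efficiency of truth over the whole domain (simulation:
        median ~0.007, 90th percentile ~0.014), and never far outside it."""
        devs = []
        for seed in range(10):
            points, truth = synth.make_calibration_table(50, noise_sd=0.01, seed=seed)
            curve = cal.fit_force_efficiency_curve(points)
            fg = np.linspace(0, 6, 200)
            devs.append(
                np.max(np.abs(
                    np.polynomial.polynomial.polyval(fg, curve.coeffs)
                    - np.polynomial.polynomial.polyval(fg, truth)
                ))
            )
        assert np.median(devs) <= 0.02
        assert max(devs) <= 0.03

    def test_same_seed_identical_table(self):
        a, _ = synth.make_calibration_table(20, noise_sd=0.02, seed=9)
        b, _ = synth.make_calibration_table(20, noise_sd=0.02, seed=9)
        assert all(x == y for x, y in zip(a, b))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            synth.make_calibration_table(4)


def test_noiseless_forward_inverse_consistency(model):
    """Scene -> ratio -> force recovers the planted force everywhere valid."""
    from tensionmap import fret, prep

    spec = [("disk", {"center": (64, 64), "radius": 20}, 2.0)]
    p = _clean_params(force_field_spec=spec)
    sc = synth.make_cell_scene(p, model)
    bg = prep.BackgroundStats(0.0, 1.0)
    rm = fret.compute_ratio_map(
        sc.channels["donor"][0] - 100.0, sc.channels["fret"][0] - 100.0, bg, bg
    )
    fm = cal.ratio_to_force(rm, model)
    inner = synth._disk_mask((128, 128), (64, 64), 18)  # clear of smoothing edge
    assert np.all(np.abs(fm.force[inner & rm.valid] - 2.0) <= 0.05)
    outer = sc.truth["mask_series"][0] & ~synth._disk_mask((128, 128), (64, 64), 22)
    assert np.all(np.abs(fm.force[outer & rm.valid]) <= 0.05)
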