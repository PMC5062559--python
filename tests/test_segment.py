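"""Segmentation, edge bands, protrusion events, and cell QC."""

import numpy as np
import pytest
from scipy import ndimage

from tensionmap import segment, synth
from tensionmap.prep import BackgroundStats


def _disk(shape, center, r):
    return synth._disk_mask(shape, center, r)


class TestSegmentCell:
    def test_recovers_planted_disk(self, model):
        p = synth.SceneParams(n_frames=2, seed=4, shading=False)
        sc = synth.make_cell_scene(p, model)
        stack = sc.channels["donor"] - 100.0 - 50.0  # dark + background
        res = segment.segment_cell(stack, bg=BackgroundStats(0.0, np.sqrt(150.0)))
        truth = sc.truth["mask_series"]
        for t in range(2):
            inter = (res.masks[t] & truth[t]).sum()
            union = (res.masks[t] | truth[t]).sum()
            assert inter / union > 0.95

    def test_active_contour_close_to_threshold_on_clean_disk(self, model):
        p = synth.SceneParams(n_frames=1, seed=8, shading=False)
        sc = synth.make_cell_scene(p, model)
        stack = sc.channels["donor"] - 150.0
        bg = BackgroundStats(0.0, np.sqrt(150.0))
        a = segment.segment_cell(stack, method="threshold", bg=bg).masks[0]
        b = segment.segment_cell(stack, method="active_contour", bg=bg).masks[0]
        iou = (a & b).sum() / (a | b).sum()
        assert iou > 0.9

    def test_keeps_largest_component_only(self):
        img = np.zeros((96, 96))
        img[_disk((96, 96), (30, 30), 15)] = 100.0
        img[_disk((96, 96), (70, 70), 6)] = 100.0
        res = segment.segment_cell(img, bg=BackgroundStats(0.0, 1.0))
        lab, n = ndimage.label(res.masks[0])
        assert n == 1
        assert res.masks[0][30, 30] and not res.masks[0][70, 70]

    def test_empty_frame_raises(self):
        with pytest.raises(ValueError, match="no cell"):
            segment.segment_cell(np.zeros((64, 64)), bg=BackgroundStats(0.0, 1.0))

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown segmentation"):
            segment.segment_cell(np.ones((32, 32)), method="watershed",
                                 bg=BackgroundStats(0.0, 0.1))


class TestRefineMask:
    def test_fills_holes_and_drops_specks(self):
        m = _disk((64, 64), (32, 32), 20)
        m[30:34, 30:34] = False  # hole
        m[2, 2] = True  # speck
        out = segment.refine_mask(m)
        assert out[31, 31]
        assert not out[2, 2]

    def test_idempotent(self, rng):
        m = _disk((64, 64), (32, 32), 18)
        m |= rng.random((64, 64)) > 0.995
        once = segment.refine_mask(m)
        assert np.array_equal(segment.refine_mask(once), once)


class TestEdgeBand:
    def test_band_width_on_disk(self):
        m = _disk((128, 128), (64, 64), 40)
        band = segment.edge_band(m, depth=10)
        edt = ndimage.distance_transform_edt(m)
        # the band covers exactly the in-mask pixels near the boundary
        assert band[m].sum() == pytest.approx((edt[m] <= 10).sum(), rel=0.05)
        assert not band[64, 64]
        assert band[m & (edt <= 5)].all() if (m & (edt <= 5)).any() else True

    def test_depth_zero_is_empty(self):
        m = _disk((32, 32), (16, 16), 10)
        assert not segment.edge_band(m, 0).any()

    def test_small_mask_warns_and_returns_mask(self):
        m = _disk((32, 32), (16, 16), 4)
        with pytest.warns(UserWarning, match="vanished"):
            band = segment.edge_band(m, depth=10)
        assert np.array_equal(band, m)

    def test_bands_nest_with_depth(self):
        m = _disk((96, 96), (48, 48), 30)
        prev = None
        for d in (2, 5, 10, 20):
            band = segment.edge_band(m, d)
            if prev is not None:
                assert np.all(band | ~prev)  # shallower band is a subset
            prev = band


class TestProtrusions:
    def _series(self, volume, duration=4, onset=2):
        masks, _ = synth.make_mask_series(
            (160, 160), 8, 35,
            protrusions=[synth.ProtrusionSpec(onset, duration, volume)],
        )
        return masks

    def test_exact_volume_threshold(self):
        below = segment.detect_protrusions(self._series(999), min_volume=1000)
        at = segment.detect_protrusions(self._series(1000), min_volume=1000)
        assert below == []
        assert len(at) == 1
        assert at[0].volume == 1000
        assert at[0].onset == 2

    def test_exact_duration_threshold(self):
        short = segment.detect_protrusions(self._series(1200, duration=2),
                                           min_frames=3)
        ok = segment.detect_protrusions(self._series(1200, duration=3),
                                        min_frames=3)
        assert short == []
        assert len(ok) == 1 and ok[0].duration == 3

    def test_static_mask_has_no_events(self):
        masks = np.broadcast_to(_disk((64, 64), (32, 32), 20), (6, 64, 64))
        assert segment.detect_protrusions(masks, min_volume=1) == []

    def test_frame_mask_partitions_voxels(self):
        ev = segment.detect_protrusions(self._series(1200), min_volume=1000)[0]
        total = sum(ev.frame_mask(t, (160, 160)).sum() for t in range(8))
        assert total == ev.volume

    def test_leading_edge_regions_within_band(self):
        masks = self._series(1200)
        evs = segment.detect_protrusions(masks, min_volume=1000)
        le = segment.leading_edge_regions(masks, evs, depth=10)
        for t in range(masks.shape[0]):
            band = segment.edge_band(masks[t], 10)
            assert not (le[t] & ~band).any()


class TestQcCells:
    def _candidate(self, **kw):
        T = kw.pop("T", 12)
        masks = np.zeros((T, 96, 96), bool)
        r = 20
        for t in range(T):
            masks[t] = _disk((96, 96), (48, 48), r + t)  # steady protrusion
        inten = np.where(masks, 500.0, 0.0)
        cand = dict(cell_id="c1", masks=masks, intensity=inten,
                    bg=BackgroundStats(0.0, 3.0))
        cand.update(kw)
        return cand

    def test_good_cell_accepted(self):
        df = segment.qc_cells([self._candidate()])
        assert bool(df.loc[0, "accepted"])
        assert df.loc[0, "reason"] == ""
        assert df.loc[0, "snr"] > 5

    def test_short_track_rejected(self):
        df = segment.qc_cells([self._candidate(T=6)])
        assert not bool(df.loc[0, "accepted"])
        assert df.loc[0, "reason"] == "duration"

    def test_border_contact_rejected(self):
        c = self._candidate()
        m = c["masks"].copy()
        m[5, 0, 40:50] = True
        c["masks"] = m
        df = segment.qc_cells([c])
        assert df.loc[0, "reason"] == "border"

    def test_cell_contact_rejected(self):
        c = self._candidate()
        others = np.zeros_like(c["masks"])
        others[:, 48, 80] = True  # adjacent to the grown cell at t=11
        c["other_masks"] = others
        df = segment.qc_cells([c])
        assert df.loc[0, "reason"] == "isolated"

    def test_static_cell_fails_protrusive(self):
        c = self._candidate()
        c["masks"] = np.broadcast_to(c["masks"][0], c["masks"].shape).copy()
        c["intensity"] = np.where(c["masks"], 500.0, 0.0)
        df = segment.qc_cells([c])
        assert df.loc[0, "reason"] == "protrusive"

    def test_dim_protrusions_fail_snr(self):
        c = self._candidate()
        c["intensity"] = np.where(c["masks"], 10.0, 0.0)  # SNR 10/3 < 5
        df = segment.qc_cells([c])
        assert df.loc[0, "reason"] == "snr"
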