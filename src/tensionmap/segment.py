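"""Cell segmentation, edge bands, protrusion detection, and cell QC.

Initial masks come from intensity-threshold segmentation (background mean
plus three background s.d.) or morphological active contours, refined by a
radius-1 closure, small-object removal, and hole filling. Edge masks are
the difference of the mask before and after a 10-pixel erosion.
Protrusions are per-frame mask gains connected through time (26-connected
in x, y, t) above a minimum space-time volume and duration. Cell-level QC
mirrors the selection used for morphodynamic analysis: a minimum track
length, no contact with the frame border or other cells, and a minimum
signal-to-noise ratio within protrusive regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology, segmentation as sk_seg

from .prep import BackgroundStats, estimate_background, make_signal_mask

__all__ = [
    "CellMaskSeries",
    "ProtrusionEvent",
    "segment_cell",
    "refine_mask",
    "edge_band",
    "detect_protrusions",
    "leading_edge_regions",
    "qc_cells",
]


@dataclass
class CellMaskSeries:
    """Per-frame binary masks of one cell."""

    masks: np.ndarray  # (T, H, W) bool
    cell_id: str = "cell"
    channel_used: str = ""

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("mask series must be (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class ProtrusionEvent:
    """A space-time connected set of mask-gain voxels."""

    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (t, y, x) arrays
    onset: int
    duration: int
    volume: int

    def frame_mask(self, t: int, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        sel = self.voxels[0] == t
        m[self.voxels[1][sel], self.voxels[2][sel]] = True
        return m


def refine_mask(mask: np.ndarray, min_object_px: int = 50) -> np.ndarray:
    """Closure (radius 1), small-object removal, hole filling; idempotent."""
    m = morphology.closing(np.asarray(mask, dtype=bool), morphology.disk(1))
    m = morphology.remove_small_objects(m, max_size=min_object_px - 1)
    return ndimage.binary_fill_holes(m)


def segment_cell(
    channels: np.ndarray | list[np.ndarray],
    method: str = "threshold",
    bg: BackgroundStats | None = None,
    k: float = 3.0,
    min_object_px: int = 50,
    keep_largest: bool = True,
    cell_id: str = "cell",
) -> CellMaskSeries:
    """Segment one cell from a background-corrected channel stack.

    Parameters
    ----------
    channels : (T, H, W) array or list of such arrays
        Segmentation channel(s); multiple channels (e.g. donor + FRET) are
        summed before thresholding.
    method : {"threshold", "active_contour"}
        Threshold: background mean + ``k`` s.d. Active contour:
        morphological Chan-Vese seeded by the threshold mask.
    bg : BackgroundStats, optional
        Reused for all frames; estimated per frame if omitted.
    """
    if isinstance(channels, (list, tuple)):
        stack = np.sum([np.asarray(c, dtype=float) for c in channels], axis=0)
    else:
        stack = np.asarray(channels, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    masks = np.zeros(stack.shape, dtype=bool)
    for t in range(stack.shape[0]):
        b = bg if bg is not None else estimate_background(stack[t])
        init = make_signal_mask(stack[t], b, k=k)
        if method == "active_contour":
            init = morphology.dilation(init, morphology.disk(2))
            init = sk_seg.morphological_chan_vese(
                stack[t], num_iter=30, init_level_set=init, smoothing=1
            ).astype(bool)
        elif method != "threshold":
            raise ValueError(f"unknown segmentation method {method!r}")
        m = refine_mask(init, min_object_px)
        if keep_largest:
            lab, n = ndimage.label(m, structure=np.ones((3, 3)))
            if n == 0:
                raise ValueError(f"no cell found in frame {t} (no component above minimum area)")
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
            m = lab == (1 + int(np.argmax(sizes)))
        masks[t] = m
    return CellMaskSeries(masks, cell_id=cell_id)


def edge_band(mask: np.ndarray, depth: int = 10) -> np.ndarray:
    """Edge mask: the cell mask minus its ``depth``-pixel (disk) erosion."""
    mask = np.asarray(mask, dtype=bool)
    if depth <= 0:
        return np.zeros_like(mask)
    eroded = morphology.erosion(mask, morphology.disk(depth))
    if not eroded.any():
        import warnings

        warnings.warn("mask vanished under erosion; edge band equals whole mask")
        return mask.copy()
    return mask & ~eroded


def detect_protrusions(
    mask_series: np.ndarray | CellMaskSeries,
    min_volume: int = 1000,
    min_frames: int = 3,
) -> list[ProtrusionEvent]:
    """Find protrusion events: time-connected mask gains above thresholds.

    Gains are ``mask[t] & ~mask[t-1]``; connectivity is 26-connectivity in
    (t, y, x). An event qualifies if its space-time volume is at least
    ``min_volume`` voxels and it spans at least ``min_frames`` consecutive
    frames (3 for leading-edge analysis, 5 for morphodynamics).
    """
    masks = mask_series.masks if isinstance(mask_series, CellMaskSeries) else np.asarray(mask_series, dtype=bool)
    if masks.shape[0] < min_frames + 1:
        return []
    gains = np.zeros_like(masks)
    gains[1:] = masks[1:] & ~masks[:-1]
    lab, n = ndimage.label(gains, structure=np.ones((3, 3, 3)))
    events = []
    for i in range(1, n + 1):
        t, y, x = np.nonzero(lab == i)
        duration = int(t.max() - t.min() + 1)
        volume = int(t.size)
        if volume >= min_volume and duration >= min_frames:
            events.append(ProtrusionEvent((t, y, x), int(t.min()), duration, volume))
    return sorted(events, key=lambda e: (e.onset, -e.volume))


def leading_edge_regions(
    mask_series: np.ndarray | CellMaskSeries,
    events: list[ProtrusionEvent],
    depth: int = 10,
) -> np.ndarray:
    """Per-frame leading-edge masks: protrusion voxels within the edge band."""
    masks = mask_series.masks if isinstance(mask_series, CellMaskSeries) else np.asarray(mask_series, dtype=bool)
    out = np.zeros_like(masks)
    shape = masks.shape[1:]
    for t in range(masks.shape[0]):
        band = edge_band(masks[t], depth)
        prot = np.zeros(shape, dtype=bool)
        for ev in events:
            prot |= ev.frame_mask(t, shape)
        out[t] = prot & band
    return out


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _touches_others(mask: np.ndarray, others: np.ndarray | None) -> bool:
    if others is None or not np.asarray(others).any():
        return False
    grown = morphology.dilation(mask, np.ones((3, 3), dtype=bool))  # 8-connectivity contact
    return bool((grown & np.asarray(others, dtype=bool)).any())


def qc_cells(
    candidates: list[dict],
    min_consecutive_frames: int = 10,
    snr_min: float = 5.0,
    min_protrusive_frames: int = 5,
    min_total_increase: int = 1000,
) -> pd.DataFrame:
    """Apply cell-selection criteria for morphodynamic analysis.

    Each candidate is a dict with keys:

    - ``cell_id``
    - ``masks`` : (T, H, W) bool mask series
    - ``intensity`` : (T, H, W) background-subtracted intensity series
    - ``bg`` : BackgroundStats of the movie
    - ``other_masks`` : optional (T, H, W) bool masks of all other cells

    Criteria: segmented for at least ``min_consecutive_frames`` consecutive
    frames; never touching the frame border or another cell; protrusive
    regions (positive frame-to-frame mask gain for >= ``min_protrusive_frames``
    frames, total pixel increase > ``min_total_increase``) with SNR — mean
    in-protrusion intensity above background divided by background s.d. —
    of at least ``snr_min``.

    Returns a per-cell DataFrame with per-criterion booleans, an ``accepted``
    flag, and the first failing ``reason``.
    """
    rows = []
    for cand in candidates:
        masks = np.asarray(cand["masks"], dtype=bool)
        bg: BackgroundStats = cand["bg"]
        present = masks.reshape(masks.shape[0], -1).any(axis=1)
        # longest run of consecutive segmented frames
        best = run = 0
        for p in present:
            run = run + 1 if p else 0
            best = max(best, run)
        ok_duration = best >= min_consecutive_frames

        ok_border = not any(_touches_border(m) for m in masks if m.any())
        others = cand.get("other_masks")
        ok_isolated = not any(
            _touches_others(masks[t], None if others is None else others[t])
            for t in range(masks.shape[0])
        )

        gains = masks[1:] & ~masks[:-1]
        gain_counts = gains.reshape(gains.shape[0], -1).sum(axis=1)
        ok_protrusive = (
            int((gain_counts > 0).sum()) >= min_protrusive_frames
            and int(gain_counts.sum()) > min_total_increase
        )
        if ok_protrusive and "intensity" in cand:
            vals = np.asarray(cand["intensity"], dtype=float)[1:][gains]
            snr = (float(vals.mean()) - 0.0) / max(bg.sigma, 1e-12)
            ok_snr = snr >= snr_min
        else:
            snr = float("nan")
            ok_snr = ok_protrusive  # no protrusive region -> cannot assess SNR
        checks = {
            "duration": ok_duration,
            "border": ok_border,
            "isolated": ok_isolated,
            "protrusive": ok_protrusive,
            "snr": ok_snr,
        }
        reason = next((k for k, v in checks.items() if not v), "")
        rows.append(
            {
                "cell_id": cand.get("cell_id", "cell"),
                **{f"ok_{k}": v for k, v in checks.items()},
                "snr": snr,
                "accepted": all(checks.values()),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
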