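"""Cell-edge morphodynamic windowing and force-protrusion correlation.

The cell interior near the boundary is partitioned into small sampling
windows organized as bands stacked inward from the edge (band 1 touches
the boundary) times positions ordered along the boundary. The number of
positions is fixed on the first frame ("constant number" propagation) and
windows are re-anchored by normalized boundary arclength — measured from a
reference point tracked to the nearest boundary point of the next frame —
as the cell deforms, so each (band, position) window is a coherent sample
of the same piece of cell edge over time.

On this grid the module computes per-window signal series, per-window edge
(protrusion) velocities from signed-distance-transform differences, the
band-wise temporal cross-correlation of two signals with circular-shift
permutation significance, the spatial localization of a signal relative to
protrusive sectors, and the per-event force-velocity regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage import measure

from .maps import ForceMap, RatioMap
from .segment import CellMaskSeries, ProtrusionEvent

__all__ = [
    "WindowGrid",
    "EdgeVelocitySeries",
    "BandCorrelation",
    "build_window_grid",
    "window_signal",
    "edge_velocity",
    "temporal_crosscorr",
    "spatial_localization_corr",
    "protrusive_positions",
    "force_velocity_regression",
    "leading_edge_force",
]


@dataclass
class WindowGrid:
    """Boundary-ordered sampling windows over a mask series.

    ``band_labels``/``pos_labels`` are (T, H, W) integer images: band 0 or
    position -1 mean the pixel is outside the grid. Band b covers
    distance-from-edge in ((b-1)*depth, b*depth] px. All bands share the
    same fixed number of positions at every frame.
    """

    band_labels: np.ndarray
    pos_labels: np.ndarray
    n_bands: int
    n_pos: int
    window_px: int
    pixel_size_nm: float
    frame_interval_s: float
    contours: list = field(default_factory=list)
    contour_pos: list = field(default_factory=list)
    ref_points: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.band_labels.shape[0]

    def window_mask(self, t: int, band: int, pos: int) -> np.ndarray:
        return (self.band_labels[t] == band) & (self.pos_labels[t] == pos)

    def band_distance_um(self, band: int) -> float:
        """Distance of a band center from the cell edge, in micrometers."""
        return (band - 0.5) * self.window_px * self.pixel_size_nm / 1000.0


@dataclass
class EdgeVelocitySeries:
    """Per-position, per-interval normal boundary velocity (nm/s).

    Positive = protrusion. Shape (n_pos, n_frames - 1); entry [p, t] is the
    motion between frames t and t+1 of band-1 position p.
    """

    velocity_nm_s: np.ndarray
    method: str = "signed-distance-difference"


@dataclass
class BandCorrelation:
    """Correlation result for one band of windows."""

    band: int
    lags: np.ndarray
    correlation: np.ndarray
    peak_lag: int
    peak_correlation: float
    p_value: float
    n_windows: int
    distance_um: float


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    cs = measure.find_contours(mask.astype(float), 0.5)
    if not cs:
        raise ValueError("mask has no boundary contour")
    return max(cs, key=len)


def build_window_grid(
    mask_series: np.ndarray | CellMaskSeries,
    window_px: int = 5,
    n_bands: int = 6,
    pixel_size_nm: float = 160.0,
    frame_interval_s: float = 5.0,
) -> WindowGrid:
    """Construct a constant-number window grid over a mask series.

    The boundary of frame 0 is divided into ``round(perimeter/window_px)``
    equal-arclength positions; that count is held fixed for all frames.
    Bands are stacked inward at ``window_px`` depth. Each in-grid pixel is
    assigned the position of its nearest boundary point.
    """
    masks = mask_series.masks if isinstance(mask_series, CellMaskSeries) else np.asarray(mask_series, dtype=bool)
    T = masks.shape[0]
    band_labels = np.zeros(masks.shape, dtype=np.int16)
    pos_labels = np.full(masks.shape, -1, dtype=np.int32)
    contours, contour_pos, refs = [], [], []
    n_pos = None
    ref_xy = None
    for t in range(T):
        contour = _longest_contour(masks[t])
        seg = np.diff(contour, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        L = s[-1]
        if n_pos is None:
            n_pos = max(1, int(round(L / window_px)))
            if L < window_px:
                raise ValueError("boundary shorter than one window")
            ref_idx = 0
        else:
            ref_idx = int(np.argmin(np.sum((contour - ref_xy) ** 2, axis=1)))
        ref_xy = contour[ref_idx]
        u = np.mod(s[:-1] - s[ref_idx], L) / L
        pos_of_pt = np.minimum((u * n_pos).astype(int), n_pos - 1)

        edt = ndimage.distance_transform_edt(masks[t])
        bands = np.ceil(edt / window_px).astype(np.int16)
        bands[~masks[t]] = 0
        bands[bands > n_bands] = 0
        band_labels[t] = bands

        yy, xx = np.nonzero(bands > 0)
        tree = cKDTree(contour[:-1])
        _, nearest = tree.query(np.column_stack([yy, xx]))
        pos_labels[t][yy, xx] = pos_of_pt[nearest]

        contours.append(contour)
        contour_pos.append(pos_of_pt)
        refs.append(tuple(ref_xy))
    return WindowGrid(
        band_labels, pos_labels, n_bands, int(n_pos), window_px,
        pixel_size_nm, frame_interval_s, contours, contour_pos, refs,
    )


def _as_masked_stack(map_series) -> np.ndarray:
    if isinstance(map_series, np.ndarray):
        return map_series.astype(float)
    return np.stack([m.masked() if isinstance(m, (RatioMap, ForceMap)) else np.asarray(m, float) for m in map_series])


def window_signal(map_series, grid: WindowGrid) -> np.ndarray:
    """Mean valid signal per window: array (n_bands, n_pos, T), NaN missing.

    ``map_series`` is a (T, H, W) array with NaN at invalid pixels, or a
    list of RatioMap/ForceMap. Windows with no valid pixel are NaN, never 0.
    """
    stack = _as_masked_stack(map_series)
    T = grid.n_frames
    out = np.full((grid.n_bands, grid.n_pos, T), np.nan)
    for t in range(T):
        img = stack[t]
        finite = np.isfinite(img)
        lab = (grid.band_labels[t].astype(np.int64) - 1) * grid.n_pos + grid.pos_labels[t]
        sel = (grid.band_labels[t] > 0) & finite
        if not sel.any():
            continue
        idx = lab[sel]
        sums = np.bincount(idx, weights=img[sel], minlength=grid.n_bands * grid.n_pos)
        cnts = np.bincount(idx, minlength=grid.n_bands * grid.n_pos)
        with np.errstate(invalid="ignore"):
            means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out[:, :, t] = means.reshape(grid.n_bands, grid.n_pos)
    return out


def edge_velocity(
    mask_series: np.ndarray | CellMaskSeries, grid: WindowGrid
) -> EdgeVelocitySeries:
    """Per-window normal boundary velocity between consecutive frames.

    For each boundary point of frame t the signed distance transform of
    frame t+1 (positive inside the mask) is sampled, minus the same-frame
    signed distance as a baseline (which cancels the sub-pixel offset
    between the marching-squares contour and the pixelated distance
    transform); the mean over the points of a boundary position is the
    outward displacement in px, converted to nm/s. Positive = protrusion.
    """
    masks = mask_series.masks if isinstance(mask_series, CellMaskSeries) else np.asarray(mask_series, dtype=bool)
    T = masks.shape[0]
    v = np.full((grid.n_pos, T - 1), np.nan)

    def _sdf(m: np.ndarray) -> np.ndarray:
        # half-pixel correction: EDT measures distance between pixel
        # centers, the boundary (0.5 contour level) sits half a pixel closer
        inner = ndimage.distance_transform_edt(m)
        outer = ndimage.distance_transform_edt(~m)
        return np.where(m, inner - 0.5, -(outer - 0.5))

    for t in range(T - 1):
        sdf_next = _sdf(masks[t + 1])
        sdf_own = _sdf(masks[t])
        contour = grid.contours[t]
        coords = [contour[:-1, 0], contour[:-1, 1]]
        vals = (
            ndimage.map_coordinates(sdf_next, coords, order=1, mode="nearest")
            - ndimage.map_coordinates(sdf_own, coords, order=1, mode="nearest")
        )
        pos = grid.contour_pos[t]
        sums = np.bincount(pos, weights=vals, minlength=grid.n_pos)
        cnts = np.bincount(pos, minlength=grid.n_pos)
        with np.errstate(invalid="ignore"):
            disp = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        v[:, t] = disp * grid.pixel_size_nm / grid.frame_interval_s
    return EdgeVelocitySeries(v)


def _xcorr_lags(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean-over-windows Pearson correlation of rows of a, b at each lag.

    a, b: (W, T) without NaN. Lag l correlates a[:, :T-l] with b[:, l:]
    (positive lag: b delayed relative to a).
    """
    W, T = a.shape
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.full(lags.size, np.nan)
    for i, l in enumerate(lags):
        if l >= 0:
            x, y = a[:, : T - l], b[:, l:]
        else:
            x, y = a[:, -l:], b[:, : T + l]
        if x.shape[1] < 3:
            continue
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc).sum(axis=1) / denom
        out[i] = np.nanmean(r)
    return out


def temporal_crosscorr(
    series_a: np.ndarray,
    series_b: np.ndarray,
    grid: WindowGrid,
    max_lag: int = 5,
    n_permutations: int = 1000,
    min_frames: int = 10,
    seed: int = 0,
) -> list[BandCorrelation]:
    """Band-wise temporal cross-correlation with permutation significance.

    ``series_a``/``series_b`` are window-signal arrays (n_bands, n_pos, T)
    (``series_b`` may also be (n_pos, T), e.g. edge velocity, applied to
    every band). Per band, each window's Pearson correlation is computed at
    each lag and averaged over windows; significance of the peak |mean r|
    comes from circularly shifting each window's ``series_b`` independently
    (``n_permutations`` draws, seeded). Bands whose windows share fewer
    than ``min_frames`` frames are skipped.
    """
    rng = np.random.default_rng(seed)
    A = np.asarray(series_a, dtype=float)
    B = np.asarray(series_b, dtype=float)
    if B.ndim == 2:
        B = np.repeat(B[None], A.shape[0], axis=0)
    if A.shape != B.shape:
        # tolerate differing frame counts (e.g. velocity has T-1 entries)
        T = min(A.shape[2], B.shape[2])
        A, B = A[:, :, :T], B[:, :, :T]
    results = []
    lags = np.arange(-max_lag, max_lag + 1)
    for band in range(1, A.shape[0] + 1):
        a, b = A[band - 1], B[band - 1]
        ok = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
        a, b = a[ok], b[ok]
        if a.shape[0] < 2 or a.shape[1] < min_frames:
            continue
        corr = _xcorr_lags(a, b, max_lag)
        ipeak = int(np.nanargmax(np.abs(corr)))
        obs = abs(corr[ipeak])
        T = a.shape[1]
        count = 0
        rows = np.arange(b.shape[0])[:, None]
        cols = np.arange(T)[None, :]
        for _ in range(n_permutations):
            shifts = rng.integers(1, T, size=b.shape[0])
            bp = b[rows, (cols - shifts[:, None]) % T]
            null = _xcorr_lags(a, bp, max_lag)
            if np.nanmax(np.abs(null)) >= obs:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        results.append(
            BandCorrelation(
                band, lags, corr, int(lags[ipeak]), float(corr[ipeak]), float(p),
                int(a.shape[0]), grid.band_distance_um(band),
            )
        )
    return results


def protrusive_positions(grid: WindowGrid, events: list[ProtrusionEvent]) -> np.ndarray:
    """(n_pos, T) indicator: position overlaps a protrusion event at frame t."""
    T = grid.n_frames
    out = np.zeros((grid.n_pos, T), dtype=bool)
    shape = grid.band_labels.shape[1:]
    for ev in events:
        for t in np.unique(ev.voxels[0]):
            fm = ev.frame_mask(int(t), shape)
            pos = grid.pos_labels[int(t)][fm & (grid.band_labels[int(t)] > 0)]
            out[np.unique(pos[pos >= 0]), int(t)] = True
    return out


def spatial_localization_corr(
    force_windows: np.ndarray,
    protrusive: np.ndarray,
    grid: WindowGrid,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[BandCorrelation]:
    """Where, relative to the edge, does a signal localize in protrusions?

    Per band, the time-averaged force of each window (position) is
    correlated across positions with the time-averaged protrusive-sector
    indicator; the peak band converts to a distance from the edge via the
    band-center geometry. Significance per band by permuting positions.
    """
    rng = np.random.default_rng(seed)
    F = np.asarray(force_windows, dtype=float)
    ind = np.asarray(protrusive, dtype=float)
    y = ind.mean(axis=1)
    results = []
    for band in range(1, F.shape[0] + 1):
        x = np.nanmean(F[band - 1], axis=1)
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        count = 0
        for _ in range(n_permutations):
            rp = np.corrcoef(x[ok], rng.permutation(y[ok]))[0, 1]
            if abs(rp) >= abs(r):
                count += 1
        p = (1 + count) / (1 + n_permutations)
        results.append(
            BandCorrelation(
                band, np.array([0]), np.array([r]), 0, r, float(p),
                int(ok.sum()), grid.band_distance_um(band),
            )
        )
    return results


def force_velocity_regression(
    mean_force: np.ndarray, mean_velocity: np.ndarray
) -> dict:
    """Pearson correlation and linear regression of force vs edge velocity.

    One value pair per protrusion event. Returns r, its two-sided p value
    and Fisher-z 95% CI, and the least-squares slope/intercept.
    """
    x = np.asarray(mean_force, dtype=float)
    y = np.asarray(mean_velocity, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 events")
    r, p = stats.pearsonr(x, y)
    lr = stats.linregress(x, y)
    if x.size > 3 and abs(r) < 1:
        z = np.arctanh(r)
        hw = 1.96 / np.sqrt(x.size - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = (float("nan"), float("nan"))
    return {
        "r": float(r), "p": float(p), "ci95": ci,
        "slope": float(lr.slope), "intercept": float(lr.intercept), "n": int(x.size),
    }


def leading_edge_force(force_maps, regions: np.ndarray) -> tuple[float, int]:
    """Mean force (pN) over valid pixels of leading-edge regions.

    ``force_maps`` is a list of ForceMap (or (T, H, W) NaN-masked array);
    ``regions`` the per-frame leading-edge masks. Returns (mean_pN, n_px);
    raises if no protrusion/leading-edge pixels exist.
    """
    stack = _as_masked_stack(force_maps)
    regions = np.asarray(regions, dtype=bool)
    T = min(stack.shape[0], regions.shape[0])
    vals = stack[:T][regions[:T]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid leading-edge pixels (no detected protrusion)")
    return float(vals.mean()), int(vals.size)
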