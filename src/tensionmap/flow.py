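"""Kymograph construction and actin retrograde-flow measurement.

A kymograph samples intensity along a line (drawn perpendicular to the
direction of migration, from the cell edge inward) in every frame,
producing a space x time image in which moving speckle features appear as
sloped stripes. Flow speed is the stripe slope converted to nm/s; by
convention retrograde flow (texture moving inward, toward increasing
distance from the edge) is reported negative.

Two estimators are provided, mirroring standard practice: the slope of a
linear feature between two endpoints (the reference method; endpoints may
come from an annotation file or the automated phase-correlation detector),
and a local gradient / structure-tensor method applied to the outermost
section of the kymograph, which serves as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Kymograph",
    "FlowMeasurement",
    "extract_kymograph",
    "measure_feature_velocity",
    "gradient_flow_speed",
    "auto_feature_endpoints",
]


@dataclass
class Kymograph:
    """Space x time intensity matrix sampled along a polyline.

    Rows index positions along the line (px spacing), columns index frames.
    """

    data: np.ndarray
    polyline: np.ndarray  # (N, 2) row/col vertices
    width: int
    pixel_size_nm: float
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class FlowMeasurement:
    """A signed flow velocity in nm/s (retrograde negative)."""

    velocity_nm_s: float
    method: str
    endpoints: tuple | None = None
    confidence: float = 1.0
    low_confidence: bool = False
    meta: dict = field(default_factory=dict)


def _sample_polyline(polyline: np.ndarray, spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced sample points and unit normals along a polyline."""
    pts = np.asarray(polyline, dtype=float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline")
    si = np.arange(0, total + 1e-9, spacing)
    samples = np.empty((si.size, 2))
    normals = np.empty((si.size, 2))
    for k, sv in enumerate(si):
        i = min(int(np.searchsorted(s, sv, side="right")) - 1, len(seg) - 1)
        t = (sv - s[i]) / max(seglen[i], 1e-12)
        samples[k] = pts[i] + t * seg[i]
        d = seg[i] / max(seglen[i], 1e-12)
        normals[k] = (-d[1], d[0])
    return samples, normals


def extract_kymograph(
    stack: np.ndarray,
    polyline: np.ndarray,
    width: int = 1,
    pixel_size_nm: float = 160.0,
    frame_interval_s: float = 1.0,
) -> Kymograph:
    """Build a kymograph by bilinear sampling along a polyline per frame.

    Intensity is averaged over ``width`` parallel offsets (at -(w-1)/2 ..
    +(w-1)/2 px along the local normal). Sampling is linear in intensity,
    so the kymograph of a linear combination of stacks is the same
    combination of kymographs.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if width < 1:
        raise ValueError("width must be >= 1")
    samples, normals = _sample_polyline(polyline)
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    h, w = stack.shape[1:]
    lo = samples + offsets.min() * normals
    hi = samples + offsets.max() * normals
    for p in (samples, lo, hi):
        if (p[:, 0].min() < -0.5 or p[:, 0].max() > h - 0.5
                or p[:, 1].min() < -0.5 or p[:, 1].max() > w - 0.5):
            raise ValueError("polyline (with width offsets) exits image bounds")
    kymo = np.zeros((samples.shape[0], stack.shape[0]))
    for t in range(stack.shape[0]):
        acc = np.zeros(samples.shape[0])
        for off in offsets:
            pts = samples + off * normals
            acc += ndimage.map_coordinates(stack[t], [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
        kymo[:, t] = acc / width
    return Kymograph(kymo, np.asarray(polyline, dtype=float), width, pixel_size_nm, frame_interval_s)


def measure_feature_velocity(
    kymo: Kymograph,
    endpoints: tuple[tuple[float, float], tuple[float, float]],
    direction_sign: float = -1.0,
) -> FlowMeasurement:
    """Velocity from the slope of a linear kymograph feature.

    ``endpoints`` are two (space_px, time_frame) points on the feature.
    ``direction_sign`` encodes the migration-direction convention:
    -1 (default) means increasing space coordinate points opposite to
    migration (inward), so features sloping toward larger space are
    retrograde and report negative.
    """
    (s1, t1), (s2, t2) = endpoints
    if t1 == t2:
        raise ValueError("feature endpoints must differ in time")
    slope_px_per_frame = (s2 - s1) / (t2 - t1)
    v = direction_sign * slope_px_per_frame * kymo.pixel_size_nm / kymo.frame_interval_s
    return FlowMeasurement(float(v), "manual-feature", endpoints=endpoints)


def _mean_column_xcorr(data: np.ndarray, gap: int) -> float:
    """Mean cross-correlation shift (px, subpixel) between columns gap apart."""
    n, T = data.shape
    acc = np.zeros(2 * n)
    for t in range(T - gap):
        a = data[:, t] - data[:, t].mean()
        b = data[:, t + gap] - data[:, t + gap].mean()
        fa, fb = np.fft.rfft(a, 2 * n), np.fft.rfft(b, 2 * n)
        acc += np.fft.irfft(fa.conj() * fb, 2 * n)
    lags = np.concatenate([np.arange(n), np.arange(-n, 0)])
    i = int(np.argmax(acc))
    ym, y0, yp = acc[(i - 1) % (2 * n)], acc[i], acc[(i + 1) % (2 * n)]
    denom = ym - 2 * y0 + yp
    frac = 0.0 if denom == 0 else float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
    return float(lags[i] + frac)


def auto_feature_endpoints(
    kymo: Kymograph,
    rows: slice | None = None,
    frame_gap: int | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Automated feature endpoints via averaged 1-D cross-correlation.

    A coarse per-frame shift from consecutive-column correlation picks a
    frame gap over which stripes move a resolvable but in-bounds distance;
    the averaged cross-correlation over all column pairs that far apart,
    with parabolic subpixel refinement, gives the stripe slope and hence
    an endpoint pair usable with :func:`measure_feature_velocity`.
    """
    data = kymo.data if rows is None else kymo.data[rows]
    row0 = 0 if rows is None else (rows.start or 0)
    n, T = data.shape
    if frame_gap is None:
        coarse = _mean_column_xcorr(data, 1)
        if abs(coarse) < 1e-3:
            frame_gap = T - 1
        else:
            frame_gap = int(np.clip(round(0.25 * n / abs(coarse)), 1, T - 1))
    shift = _mean_column_xcorr(data, frame_gap)
    s0 = row0 + n / 2
    return ((s0, 0.0), (s0 + shift, float(frame_gap)))


def gradient_flow_speed(
    kymo: Kymograph,
    rows: slice | None = None,
    direction_sign: float = -1.0,
    smooth_px: float = 1.0,
    coherence_min: float = 0.2,
) -> FlowMeasurement:
    """Flow speed from local spatiotemporal gradient orientation.

    The structure tensor of the (optionally outer-band restricted)
    kymograph is averaged over the region; the eigenvector of its smaller
    eigenvalue gives the dominant stripe direction, whose slope converts
    to nm/s. The normalized eigenvalue contrast (coherence) flags
    near-isotropic texture (no dominant orientation) as low confidence.
    """
    data = kymo.data if rows is None else kymo.data[rows]
    if data.size == 0:
        raise ValueError("empty kymograph region")
    img = ndimage.gaussian_filter(data, smooth_px)
    gs = ndimage.sobel(img, axis=0) / 8.0  # d/d(space)
    gt = ndimage.sobel(img, axis=1) / 8.0  # d/d(time)
    # trim borders where sobel pads
    gs, gt = gs[1:-1, 1:-1], gt[1:-1, 1:-1]
    jxx, jxt, jtt = np.mean(gs * gs), np.mean(gs * gt), np.mean(gt * gt)
    j = np.array([[jxx, jxt], [jxt, jtt]])
    evals, evecs = np.linalg.eigh(j)
    coherence = float((evals[1] - evals[0]) / max(evals[1] + evals[0], 1e-30))
    v_s, v_t = evecs[:, 0]  # smaller-eigenvalue eigenvector: along stripes
    if abs(v_t) < 1e-12:
        slope = np.inf
    else:
        slope = v_s / v_t  # px per frame along the line
    v = direction_sign * slope * kymo.pixel_size_nm / kymo.frame_interval_s
    return FlowMeasurement(
        float(v),
        "gradient",
        confidence=coherence,
        low_confidence=coherence < coherence_min,
        meta={"slope_px_per_frame": float(slope)},
    )
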