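"""Ratiometric FRET maps, photobleach correction, and force summaries.

For a single-chain sensor the FRET ratio is simply the acceptor-emission
image (donor excitation) divided by the donor-emission image. Both
channels are pre-filtered with a 3x3 Gaussian kernel and a pixel is valid
only if both smoothed, background-subtracted channels exceed three times
the frame's background s.d. — this both excludes background and avoids
division-of-small-integer artifacts.

Acceptor photodamage appears as an exponential decay of the whole-cell
mean FRET ratio; a single or double exponential is fitted to that series
(chosen by small-sample corrected AIC) and frames are divided by the
fitted decay normalized to 1 at the first time point, which is therefore
never altered. Reported force quantification defaults to the first frame
so it cannot depend on the correction at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .calibration import CalibrationModel, ratio_to_force
from .maps import ForceMap, RatioMap
from .prep import BackgroundStats

__all__ = [
    "BleachFit",
    "CellForceSummary",
    "compute_ratio_map",
    "correct_photobleach",
    "apply_bleach_correction",
    "force_map",
    "whole_cell_summary",
]

# 3x3 Gaussian kernel, sigma = 1 px, truncated and renormalized
_K1 = np.exp(-0.5 * np.arange(-1, 2) ** 2)
KERNEL_3X3 = np.outer(_K1, _K1) / np.outer(_K1, _K1).sum()


def smooth_3x3(image: np.ndarray) -> np.ndarray:
    """3x3 Gaussian pre-filter (sigma 1 px, renormalized truncation)."""
    return ndimage.convolve(np.asarray(image, dtype=float), KERNEL_3X3, mode="nearest")


@dataclass
class BleachFit:
    """Fitted photobleach decay of the whole-cell mean FRET ratio.

    ``model`` is "single" or "double"; rates are per frame. ``factors``
    are the per-frame correction divisors, normalized so factors[0] == 1.
    """

    model: str
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    factors: np.ndarray
    aicc: float
    converged: bool = True

    @property
    def rate(self) -> float:
        """Dominant (largest-amplitude) decay rate, per frame."""
        i = int(np.argmax(np.abs(self.amplitudes)))
        return self.rates[i]


@dataclass
class CellForceSummary:
    cell_id: str
    frame_policy: str
    mean_ratio: float
    mean_efficiency: float
    mean_force_pN: float
    n_pixels: int


def compute_ratio_map(
    donor: np.ndarray,
    fret: np.ndarray,
    bg_donor: BackgroundStats,
    bg_fret: BackgroundStats,
    k: float = 3.0,
    frame: int = 0,
) -> RatioMap:
    """Per-pixel FRET ratio with the 3-sigma inclusion rule.

    ``donor``/``fret`` must already be corrected and background-subtracted;
    validity requires both 3x3-smoothed channels to exceed ``k`` times the
    respective frame background s.d.
    """
    donor = np.asarray(donor, dtype=float)
    fret = np.asarray(fret, dtype=float)
    if donor.shape != fret.shape:
        raise ValueError("donor and FRET frame shapes differ")
    ds = smooth_3x3(donor)
    fs = smooth_3x3(fret)
    valid = (ds > k * bg_donor.sigma) & (fs > k * bg_fret.sigma) & (ds > 0)
    ratio = np.full(donor.shape, np.nan)
    ratio[valid] = fs[valid] / ds[valid]
    return RatioMap(ratio=ratio, valid=valid, frame=frame, bg=(bg_donor, bg_fret))


def _single(t, a, k):
    return a * np.exp(-k * t)


def _double(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _aicc(resid: np.ndarray, n_par: int) -> float:
    n = resid.size
    rss = float(np.sum(resid**2))
    aic = n * np.log(max(rss / n, 1e-300)) + 2 * n_par
    if n - n_par - 1 > 0:
        aic += 2 * n_par * (n_par + 1) / (n - n_par - 1)
    return aic


def correct_photobleach(
    ratio_series: np.ndarray,
    model: str = "auto",
) -> tuple[np.ndarray, BleachFit]:
    """Fit exponential bleaching to a whole-cell mean-ratio series.

    Parameters
    ----------
    ratio_series : 1-D array
        Mean FRET/donor ratio per frame for one cell (>= 5 finite frames).
    model : {"auto", "single", "double"}
        "auto" picks single vs double exponential by corrected AIC.

    Returns
    -------
    corrected : ndarray
        ``ratio_series / factors`` with factors normalized to 1 at frame 0.
    fit : BleachFit
        ``converged`` False means the series is returned uncorrected.
    """
    y = np.asarray(ratio_series, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need >= 5 frames with valid mean ratios")
    t = np.arange(y.size, dtype=float)

    fits: dict[str, tuple] = {}
    try:
        p, _ = curve_fit(
            _single, t[ok], y[ok], p0=(y[ok][0], 0.01),
            bounds=([0, 0], [np.inf, np.inf]), maxfev=20_000,
        )
        fits["single"] = (p, _aicc(y[ok] - _single(t[ok], *p), 2))
    except RuntimeError:
        pass
    if model in ("auto", "double"):
        try:
            a0 = y[ok][0]
            p, _ = curve_fit(
                _double, t[ok], y[ok], p0=(0.6 * a0, 0.1, 0.4 * a0, 0.005),
                bounds=([0, 0, 0, 0], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=40_000,
            )
            fits["double"] = (p, _aicc(y[ok] - _double(t[ok], *p), 4))

        except RuntimeError:
            pass
    if model in fits:
        chosen = model
    elif fits:
        chosen = min(fits, key=lambda m: fits[m][1])
    else:
        flat = BleachFit("none", (float(np.nanmean(y)),), (0.0,),
                         np.ones_like(y), float("inf"), converged=False)
        return y.copy(), flat

    p, aicc = fits[chosen]
    fn = _single if chosen == "single" else _double
    decay = fn(t, *p)
    factors = decay / decay[0]
    factors = np.where(factors > 1e-6, factors, 1.0)
    if chosen == "single":
        amps, rates = (float(p[0]),), (float(p[1]),)
    else:
        amps, rates = (float(p[0]), float(p[2])), (float(p[1]), float(p[3]))
    fit = BleachFit(chosen, amps, rates, factors, aicc)
    return y / factors, fit


def apply_bleach_correction(ratio_maps: list[RatioMap], fit: BleachFit) -> list[RatioMap]:
    """Divide each frame's ratio map by its fitted bleach factor."""
    out = []
    for rm in ratio_maps:
        f = fit.factors[rm.frame] if rm.frame < fit.factors.size else fit.factors[-1]
        out.append(RatioMap(rm.ratio / f, rm.valid.copy(), rm.frame, rm.bg))
    return out


def force_map(ratio_map: RatioMap, model: CalibrationModel) -> ForceMap:
    """Calibrated per-pixel force map (pN) for one frame."""
    return ratio_to_force(ratio_map, model)


def whole_cell_summary(
    ratio_maps: list[RatioMap],
    cell_mask: np.ndarray,
    model: CalibrationModel,
    cell_id: str = "cell",
    frame_policy: str = "first",
) -> CellForceSummary:
    """Whole-cell mean ratio/efficiency/force over valid in-mask pixels.

    ``frame_policy`` "first" (default) uses only the first frame, keeping
    the numbers independent of photobleach correction; "all" averages over
    every frame.
    """
    if frame_policy == "first":
        maps = ratio_maps[:1]
    elif frame_policy == "all":
        maps = ratio_maps
    else:
        raise ValueError(f"unknown frame policy {frame_policy!r}")
    mask3 = np.asarray(cell_mask, dtype=bool)
    vals = []
    for rm in maps:
        m = mask3[rm.frame] if mask3.ndim == 3 else mask3
        sel = rm.valid & m
        vals.append(rm.ratio[sel])
    vals = np.concatenate(vals) if vals else np.array([])
    if vals.size == 0:
        raise ValueError("no valid in-mask pixels (no-signal)")
    mean_ratio = float(vals.mean())
    eff = float(np.mean(model.line.efficiency(vals)))
    force = float(np.mean(model.inverse.force(vals)))
    return CellForceSummary(cell_id, frame_policy, mean_ratio, eff, force, int(vals.size))
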