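"""Force calibration for a ratiometric molecular tension sensor.

The tension-sensor module reports tensile force through FRET: stretching the
elastic linker separates donor and acceptor, lowering FRET efficiency. The
calibration chain has three parts:

1. ``E(f)`` — a quartic polynomial fitted to tabulated (force, efficiency)
   calibration points for the sensor module, monotone non-increasing over
   the sensor's working range (~0-6 pN).
2. ``E(R)`` — a linear map from the instrument-specific FRET ratio ``R``
   to efficiency, fitted on reference constructs of known efficiency
   (conventionally E = 0.55 and E = 0.11 for the mTFP/mVenus pair, between
   which E(R) is close to linear given the ~6.0 nm Förster distance).
3. ``f(R)`` — the numeric inverse: equating E(f) with E(R) at many points
   along the calibration curve, solving for f by bracketed bisection, and
   fitting a quartic to the resulting (R, f) pairs. Neither E(f) nor f(R)
   admits a closed-form inverse.

Forces are clamped to the calibrated range; ratios outside the calibrated
ratio domain saturate at the nearest endpoint and are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .maps import ForceMap, RatioMap

__all__ = [
    "CalibPoint",
    "ForceEfficiencyCurve",
    "RatioEfficiencyLine",
    "ForceRatioPolynomial",
    "CalibrationModel",
    "CalibrationError",
    "fit_force_efficiency_curve",
    "fit_ratio_efficiency_line",
    "build_force_inverse",
    "build_calibration_model",
    "ratio_to_force",
    "load_calibration_table",
    "load_reference_table",
    "default_calibration_model",
]

#: Förster distance of the mTFP1/mVenus pair, nm.
FORSTER_DISTANCE_NM = 6.0


class CalibrationError(ValueError):
    """Raised for underdetermined, degenerate, or inconsistent calibrations."""


@dataclass(frozen=True)
class CalibPoint:
    """One tabulated calibration measurement: force (pN) vs FRET efficiency."""

    force: float
    efficiency: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.force) and np.isfinite(self.efficiency)):
            raise CalibrationError("non-finite calibration point")
        if self.force < 0:
            raise CalibrationError(f"negative force {self.force} pN")
        if not (0.0 < self.efficiency < 1.0):
            raise CalibrationError(
                f"efficiency {self.efficiency} outside (0, 1)"
            )


@dataclass
class ForceEfficiencyCurve:
    """Quartic E(f): FRET efficiency as a function of force.

    ``coeffs`` are polynomial coefficients in ascending order (c0..c4);
    ``domain`` is the calibrated force range in pN.
    """

    coeffs: np.ndarray
    domain: tuple[float, float]
    residual_rms: float = 0.0
    monotone: bool = True

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (5,):
            raise CalibrationError("quartic curve needs 5 coefficients")

    def efficiency(self, force: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(force, self.coeffs)

    __call__ = efficiency

    def derivative(self, force: np.ndarray | float) -> np.ndarray | float:
        dcoef = np.polynomial.polynomial.polyder(self.coeffs)
        return np.polynomial.polynomial.polyval(force, dcoef)


@dataclass
class RatioEfficiencyLine:
    """Linear map E = slope * R + intercept between ratio and efficiency.

    Valid in the efficiency range where the FRET-ratio/efficiency relation
    is approximately linear for this fluorophore pair (default 0.11-0.55).
    """

    slope: float
    intercept: float
    valid_efficiency_range: tuple[float, float] = (0.11, 0.55)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError("ratio-efficiency slope must be positive")

    def efficiency(self, ratio: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(ratio, dtype=float) + self.intercept

    def ratio(self, efficiency: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(efficiency, dtype=float) - self.intercept) / self.slope


@dataclass
class ForceRatioPolynomial:
    """Quartic f(R) giving force from FRET ratio, with saturation.

    Higher FRET ratio means higher FRET means a more relaxed sensor, so
    f(R) is monotone non-increasing on ``ratio_domain``. Ratios outside
    the domain clamp to the nearest endpoint force (0 or ``f_max``).
    """

    coeffs: np.ndarray
    ratio_domain: tuple[float, float]
    f_max: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (5,):
            raise CalibrationError("quartic inverse needs 5 coefficients")
        if self.ratio_domain[0] >= self.ratio_domain[1]:
            raise CalibrationError("empty ratio domain")

    def force(self, ratio: np.ndarray | float) -> np.ndarray:
        r = np.asarray(ratio, dtype=float)
        rc = np.clip(r, self.ratio_domain[0], self.ratio_domain[1])
        f = np.polynomial.polynomial.polyval(rc, self.coeffs)
        return np.clip(f, 0.0, self.f_max)

    __call__ = force

    def saturated(self, ratio: np.ndarray | float) -> np.ndarray:
        """Boolean mask of ratios outside the calibrated ratio domain."""
        r = np.asarray(ratio, dtype=float)
        return (r < self.ratio_domain[0]) | (r > self.ratio_domain[1])


@dataclass
class CalibrationModel:
    """The full calibration chain E(f), E(R), and the numeric inverse f(R)."""

    curve: ForceEfficiencyCurve
    line: RatioEfficiencyLine
    inverse: ForceRatioPolynomial
    forster_distance: float = FORSTER_DISTANCE_NM
    provenance: dict = field(default_factory=dict)

    def ratio_for_force(self, force: np.ndarray | float) -> np.ndarray | float:
        """Forward model: expected FRET ratio at a given force (pN)."""
        return self.line.ratio(self.curve.efficiency(force))

    @property
    def zero_force_ratio(self) -> float:
        return float(self.ratio_for_force(self.curve.domain[0]))

    @property
    def f_max(self) -> float:
        return self.inverse.f_max

    def to_json(self, path: str | Path) -> None:
        payload = {
            "curve": {
                "coeffs": self.curve.coeffs.tolist(),
                "domain": list(self.curve.domain),
                "residual_rms": self.curve.residual_rms,
                "monotone": self.curve.monotone,
            },
            "line": {
                "slope": self.line.slope,
                "intercept": self.line.intercept,
                "valid_efficiency_range": list(self.line.valid_efficiency_range),
            },
            "inverse": {
                "coeffs": self.inverse.coeffs.tolist(),
                "ratio_domain": list(self.inverse.ratio_domain),
                "f_max": self.inverse.f_max,
            },
            "forster_distance_nm": self.forster_distance,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            curve=ForceEfficiencyCurve(
                np.asarray(d["curve"]["coeffs"]),
                tuple(d["curve"]["domain"]),
                d["curve"].get("residual_rms", 0.0),
                d["curve"].get("monotone", True),
            ),
            line=RatioEfficiencyLine(
                d["line"]["slope"],
                d["line"]["intercept"],
                tuple(d["line"]["valid_efficiency_range"]),
            ),
            inverse=ForceRatioPolynomial(
                np.asarray(d["inverse"]["coeffs"]),
                tuple(d["inverse"]["ratio_domain"]),
                d["inverse"]["f_max"],
            ),
            forster_distance=d.get("forster_distance_nm", FORSTER_DISTANCE_NM),
            provenance=d.get("provenance", {}),
        )


def _as_points(points: Iterable) -> list[CalibPoint]:
    out = []
    for p in points:
        if isinstance(p, CalibPoint):
            out.append(p)
        else:
            out.append(CalibPoint(float(p[0]), float(p[1])))
    return out


def fit_force_efficiency_curve(points: Iterable) -> ForceEfficiencyCurve:
    """Least-squares quartic fit of FRET efficiency against force.

    Parameters
    ----------
    points : iterable of CalibPoint or (force_pN, efficiency) pairs
        At least 5 points spanning at least 3 pN.

    Returns
    -------
    ForceEfficiencyCurve
        With ``residual_rms`` of the fit and ``monotone`` flagging whether
        the fitted quartic is non-increasing over the calibrated domain.
    """
    pts = _as_points(points)
    if len(pts) < 5:
        raise CalibrationError(
            f"quartic fit underdetermined: {len(pts)} points (need >= 5)"
        )
    f = np.array([p.force for p in pts])
    e = np.array([p.efficiency for p in pts])
    if f.max() - f.min() < 3.0:
        raise CalibrationError(
            f"calibration forces span only {f.max() - f.min():.2f} pN (need >= 3)"
        )
    coeffs = np.polynomial.polynomial.polyfit(f, e, 4)
    resid = e - np.polynomial.polynomial.polyval(f, coeffs)
    domain = (float(f.min()), float(f.max()))
    grid = np.linspace(*domain, 512)
    dcoef = np.polynomial.polynomial.polyder(coeffs)
    mono = bool(np.all(np.polynomial.polynomial.polyval(grid, dcoef) <= 1e-12))
    return ForceEfficiencyCurve(
        coeffs, domain, residual_rms=float(np.sqrt(np.mean(resid**2))), monotone=mono
    )


def fit_ratio_efficiency_line(
    refs: Sequence[tuple[float, float]],
    valid_efficiency_range: tuple[float, float] = (0.11, 0.55),
) -> RatioEfficiencyLine:
    """Ordinary least-squares line E = a*R + b from reference measurements.

    ``refs`` are (measured ratio, known efficiency) pairs; with exactly two
    distinct references the line interpolates both exactly.
    """
    refs = list(refs)
    if len(refs) < 2:
        raise CalibrationError("need >= 2 reference measurements")
    r = np.array([x[0] for x in refs], dtype=float)
    e = np.array([x[1] for x in refs], dtype=float)
    if not np.all((e > 0) & (e < 1)):
        raise CalibrationError("reference efficiencies must lie in (0, 1)")
    if np.ptp(r) == 0:
        raise CalibrationError("degenerate regression: all ratios identical")
    b, a = np.polynomial.polynomial.polyfit(r, e, 1)
    return RatioEfficiencyLine(float(a), float(b), valid_efficiency_range)


def build_force_inverse(
    curve: ForceEfficiencyCurve,
    line: RatioEfficiencyLine,
    n_points: int = 1000,
) -> ForceRatioPolynomial:
    """Numerically invert the calibration chain to a quartic f(R).

    At ``n_points`` points along the calibration curve the equality
    ``curve(f) == line(R)`` is solved for f by bracketed bisection
    (Brent's method on the monotone domain), and a quartic is fitted to
    the resulting (R, f) pairs.
    """
    if not curve.monotone:
        raise CalibrationError("curve is not monotone on its domain")
    f_lo, f_hi = curve.domain
    f_grid = np.linspace(f_lo, f_hi, n_points)
    ratios = np.asarray(line.ratio(curve.efficiency(f_grid)), dtype=float)
    if not np.all(np.isfinite(ratios)) or np.any(ratios <= 0):
        raise CalibrationError(
            "calibration curve and ratio line are inconsistent: the line "
            "maps the curve's efficiencies to non-positive FRET ratios"
        )

    forces = np.empty(n_points)
    failures = 0
    for i, r in enumerate(ratios):
        target = line.efficiency(r)

        def g(f: float, t: float = target) -> float:
            return float(curve.efficiency(f)) - t

        ga, gb = g(f_lo), g(f_hi)
        if ga == 0.0:
            forces[i] = f_lo
        elif gb == 0.0:
            forces[i] = f_hi
        elif ga * gb > 0:
            failures += 1
            forces[i] = np.nan
        else:
            forces[i] = brentq(g, f_lo, f_hi, xtol=1e-10)
    if failures > 0.01 * n_points:
        raise CalibrationError(
            f"root finding failed at {failures}/{n_points} sample points; "
            "calibration curve and ratio line are inconsistent"
        )
    ok = np.isfinite(forces)
    coeffs = np.polynomial.polynomial.polyfit(ratios[ok], forces[ok], 4)
    r_lo, r_hi = float(ratios.min()), float(ratios.max())
    return ForceRatioPolynomial(coeffs, (r_lo, r_hi), f_max=float(f_hi))


def build_calibration_model(
    points: Iterable,
    refs: Sequence[tuple[float, float]],
    n_points: int = 1000,
    provenance: dict | None = None,
) -> CalibrationModel:
    """Fit the full calibration chain from a table and reference constructs."""
    curve = fit_force_efficiency_curve(points)
    line = fit_ratio_efficiency_line(refs)
    inverse = build_force_inverse(curve, line, n_points=n_points)
    return CalibrationModel(curve, line, inverse, provenance=provenance or {})


def ratio_to_force(ratio_map: RatioMap, model: CalibrationModel) -> ForceMap:
    """Convert a per-pixel FRET-ratio map to a per-pixel force map (pN).

    Invalid ratio pixels stay invalid; out-of-domain ratios clamp to the
    endpoint force and are flagged saturated. Forces lie in [0, f_max].
    """
    force = np.full(ratio_map.shape, np.nan)
    sat = np.zeros(ratio_map.shape, dtype=bool)
    v = ratio_map.valid
    force[v] = model.inverse.force(ratio_map.ratio[v])
    sat[v] = model.inverse.saturated(ratio_map.ratio[v])
    return ForceMap(force=force, valid=v.copy(), saturated=sat, frame=ratio_map.frame)


def load_calibration_table(path: str | Path) -> list[CalibPoint]:
    """Read a calibration table CSV with columns ``force_pN, efficiency``."""
    df = pd.read_csv(path)
    return [CalibPoint(r.force_pN, r.efficiency) for r in df.itertuples()]


def load_reference_table(path: str | Path) -> list[tuple[float, float]]:
    """Read a reference-construct CSV with columns ``construct, ratio, efficiency``.

    Replicate rows per construct are allowed; all rows enter the regression.
    """
    df = pd.read_csv(path)
    return list(zip(df["ratio"].astype(float), df["efficiency"].astype(float)))


def default_calibration_model(n_points: int = 1000) -> CalibrationModel:
    """Calibration model fitted from the packaged synthetic default tables.

    The packaged tables are synthetic: they reproduce the qualitative shape
    of a 0-6 pN tension-sensor module (high-FRET plateau at low force,
    E falling from 0.30 to 0.05) and two-point mTFP/mVenus references, not
    any instrument's measured values.
    """
    data = resources.files("tensionmap") / "data"
    with resources.as_file(data / "synthetic_calibration_table.csv") as p:
        points = load_calibration_table(p)
    with resources.as_file(data / "synthetic_reference_constructs.csv") as p:
        refs = load_reference_table(p)
    return build_calibration_model(
        points, refs, n_points=n_points, provenance={"source": "packaged synthetic default"}
    )
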