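"""Synthetic TIRF scenes with planted ground truth.

Every stage of the pipeline is tested against scenes rendered by this
module: multi-channel FRET time-lapse stacks (donor, FRET, actin), TIRF
z-stacks with defocus blur, bead stacks for chromatic calibration, and
antibody-stain channels with a planted pixel correlation. The forward
model mirrors the assumptions the processing chain inverts:

* per-pixel FRET ratio equals the calibration forward model
  ``R = line^-1(curve(f_true))`` before noise;
* acceptor photodamage appears as exponential decay of the FRET ratio
  with the donor held constant;
* the camera adds a dark level and Gaussian read noise on top of Poisson
  shot noise, and illumination is shaded by a smooth multiplicative field;
* actin speckle texture is advected rigidly at the planted flow velocity
  using subpixel sampling from a static canvas (exact velocity truth).

Defaults mirror a 100x/1.49 NA TIRF setup with an EM-CCD: 160 nm pixels,
3-20 s frame intervals for FRET movies and 1 s for actin-flow movies.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .calibration import CalibPoint, CalibrationModel

__all__ = [
    "SceneParams",
    "ProtrusionSpec",
    "SyntheticScene",
    "make_cell_scene",
    "make_mask_series",
    "make_zstack_scene",
    "make_stain_scene",
    "make_calibration_table",
    "DEFAULT_TRUTH_COEFFS",
]

#: Ascending coefficients of the default ground-truth quartic E(f) used by
#: :func:`make_calibration_table` (E: 0.30 at 0 pN -> 0.05 at 6 pN, monotone,
#: gentle high-FRET plateau). Matches the packaged synthetic default table.
DEFAULT_TRUTH_COEFFS = np.array(
    [0.29935229, -0.028214856, -0.0086030881, 0.0012496168, -3.0645907e-05]
)


@dataclass(frozen=True)
class ProtrusionSpec:
    """A scheduled protrusion with an exactly planted space-time gain volume.

    ``volume`` pixels are added to the mask over ``duration`` consecutive
    frames starting at ``onset``, stacked layer by layer on the cell edge in
    the given cardinal ``direction`` so the gain voxels form one space-time
    connected component of exactly ``volume`` voxels.
    """

    onset: int
    duration: int
    volume: int
    direction: Literal["N", "E", "S", "W"] = "N"
    width: int = 30


@dataclass
class SceneParams:
    """Parameters of a synthetic FRET time-lapse scene.

    Camera counts are EM-CCD-like; ``pixel_size_nm`` defaults to 160 nm
    (16 um camera pixels at 100x). ``force_field_spec`` may be a scalar
    (uniform pN inside the cell), a full (H, W) array in pN, the string
    ``"random"`` (smooth random field in ~0.5-5.5 pN), or a list of
    ``(kind, params, pN)`` regions with kind in {"disk", "ring", "band"}
    ("band" selects pixels by distance-from-edge in px).
    """

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 10
    pixel_size_nm: float = 160.0
    frame_interval_s: float = 5.0
    dark_level: float = 100.0
    read_noise_sd: float = 3.0
    background_signal: float = 50.0
    shading_amplitude: float = 0.15
    donor_level: float = 1500.0
    bleach_rate: float = 0.01
    cell_radius: float = 40.0
    cell_center: tuple[float, float] | None = None
    force_field_spec: object = 0.0
    flow_velocity_nm_s: float = -100.0
    actin_level: float = 1000.0
    speckle_sigma_px: float = 1.5
    protrusions: Sequence[ProtrusionSpec] = ()
    optics_blur_px: float = 0.0
    noise: bool = True
    bleach: bool = True
    shading: bool = True
    seed: int = 0

    def replace(self, **kw) -> "SceneParams":
        return replace(self, **kw)


@dataclass
class SyntheticScene:
    """Rendered channel stacks plus the planted ground truth."""

    channels: dict[str, np.ndarray]
    truth: dict
    params: object = None

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _protrusion_layers(
    mask: np.ndarray, spec: ProtrusionSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ordered pixel coordinates stacking outward from the edge of ``mask``.

    Returns per-layer (rows, cols) in fill order; rotating the mask maps
    the four cardinal directions onto a single "grow upward" primitive.
    """
    k = {"N": 0, "W": 1, "S": 2, "E": 3}[spec.direction]
    m = np.rot90(mask, k)
    h, w = m.shape
    cc = w // 2
    cols = np.arange(cc - spec.width // 2, cc - spec.width // 2 + spec.width)
    # topmost occupied row per column; protrusion stacks above it
    tops = np.array([np.argmax(m[:, c]) if m[:, c].any() else h for c in cols])
    max_layers = int(np.ceil(spec.volume / spec.width)) + 1
    layers = []
    for lay in range(1, max_layers + 1):
        rows = tops - lay
        keep = rows >= 0
        layers.append((rows[keep], cols[keep]))
    return layers, m.shape, k


def _rot_coords_back(rows, cols, shape_rot, k):
    """Invert the ``np.rot90(a, k)`` index mapping for pixel coordinates."""
    h, w = shape_rot
    for _ in range(k % 4):
        # one inverse rot90 step: a_rot90[i, j] == a[j, w_orig - 1 - i]
        rows, cols = cols, h - 1 - rows
        h, w = w, h
    return np.asarray(rows), np.asarray(cols)


def make_mask_series(
    shape: tuple[int, int],
    n_frames: int,
    radius: float,
    center: tuple[float, float] | None = None,
    protrusions: Sequence[ProtrusionSpec] = (),
) -> tuple[np.ndarray, dict]:
    """Binary cell-mask series: a disk plus scheduled protrusions.

    Returns (masks (T, H, W) bool, truth) where truth records per-event
    planted gain-voxel counts and onset/duration exactly as rendered.
    """
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    base = _disk_mask(shape, center, radius)
    masks = np.repeat(base[None], n_frames, axis=0)
    events = []
    for spec in protrusions:
        layers, shape_rot, k = _protrusion_layers(base, spec)
        order_r, order_c = [], []
        for rows, cols in layers:
            rr, cc = _rot_coords_back(rows.copy(), cols.copy(), shape_rot, k)
            order_r.extend(rr.tolist())
            order_c.extend(cc.tolist())
        if len(order_r) < spec.volume:
            raise ValueError(
                f"protrusion volume {spec.volume} does not fit between the cell "
                f"edge and the image border (room for {len(order_r)} voxels); "
                "increase width or image size"
            )
        order_r = np.array(order_r[: spec.volume])
        order_c = np.array(order_c[: spec.volume])
        planted = len(order_r)
        # cumulative pixel counts per event frame, as even as possible
        cum = np.round(planted * (np.arange(spec.duration) + 1) / spec.duration).astype(int)
        for j, t in enumerate(range(spec.onset, min(spec.onset + spec.duration, n_frames))):
            idx = cum[j]
            masks[t:, order_r[:idx], order_c[:idx]] = True
        events.append(
            {
                "onset": spec.onset,
                "duration": min(spec.duration, n_frames - spec.onset),
                "volume": planted,
                "direction": spec.direction,
            }
        )
    return masks, {"events": events, "base_mask": base}


def _shading_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative illumination field, normalized to unit mean."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    u = xx / max(shape[1] - 1, 1) - 0.5
    v = yy / max(shape[0] - 1, 1) - 0.5
    s = 1.0 + amplitude * (u + 0.4 * v) - 0.5 * amplitude * (u**2 + v**2)
    return s / s.mean()


def _random_force_field(shape, rng, lo=0.5, hi=5.5, smooth_px=4.0) -> np.ndarray:
    g = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_px)
    g = (g - g.min()) / max(g.max() - g.min(), 1e-12)
    return lo + (hi - lo) * g


def force_field_from_spec(
    spec: object, shape: tuple[int, int], mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Materialize a per-pixel force field (pN) from a ``force_field_spec``."""
    if isinstance(spec, str):
        if spec == "random":
            return _random_force_field(shape, rng)
        raise ValueError(f"unknown force field spec {spec!r}")
    if isinstance(spec, np.ndarray):
        if spec.shape != shape:
            raise ValueError("force field array shape mismatch")
        return spec.astype(float)
    if np.isscalar(spec):
        return np.full(shape, float(spec))
    ff = np.zeros(shape)
    edt = ndimage.distance_transform_edt(mask)
    for kind, p, pn in spec:
        if kind == "disk":
            reg = _disk_mask(shape, p["center"], p["radius"])
        elif kind == "ring":
            d = _disk_mask(shape, p["center"], p["r_out"])
            reg = d & ~_disk_mask(shape, p["center"], p["r_in"])
        elif kind == "band":
            reg = (edt > p["lo"]) & (edt <= p["hi"]) & mask
        else:
            raise ValueError(f"unknown region kind {kind!r}")
        ff[reg] = pn
    return ff


def _camera(
    clean: np.ndarray,
    shading: np.ndarray,
    dark: float,
    read_sd: float,
    rng: np.random.Generator,
    noise: bool,
) -> np.ndarray:
    shaded = clean * shading
    if not noise:
        return shaded + dark
    shot = rng.poisson(np.clip(shaded, 0, None)).astype(float)
    return shot + dark + rng.normal(0.0, read_sd, size=clean.shape)


def _speckle_texture(shape, sigma_px, rng) -> np.ndarray:
    t = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
    return t


def make_cell_scene(params: SceneParams, model: CalibrationModel) -> SyntheticScene:
    """Render a donor/FRET/actin time-lapse with planted per-pixel forces.

    The noiseless per-pixel ratio equals the calibration forward model at
    the planted force; the FRET channel then decays exponentially at
    ``bleach_rate`` per frame with the donor held constant, and both pass
    through shading, shot noise, dark level, and read noise.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    center = params.cell_center or (shape[0] / 2, shape[1] / 2)
    masks, mask_truth = make_mask_series(
        shape, params.n_frames, params.cell_radius, center, params.protrusions
    )
    force = force_field_from_spec(params.force_field_spec, shape, masks[0], rng)
    f_lo, f_hi = model.curve.domain
    if force.min() < f_lo - 1e-9 or force.max() > f_hi + 1e-9:
        raise ValueError(
            f"planted forces [{force.min():.2f}, {force.max():.2f}] pN outside "
            f"calibrated domain [{f_lo}, {f_hi}]"
        )
    ratio_true = np.asarray(model.ratio_for_force(force), dtype=float)
    shading = (
        _shading_field(shape, params.shading_amplitude)
        if params.shading
        else np.ones(shape)
    )
    texture = _speckle_texture((shape[0] + 4 * abs(int(_flow_px(params)) * params.n_frames) + 8, shape[1]), params.speckle_sigma_px, rng)

    donor = np.empty((params.n_frames,) + shape)
    fret = np.empty_like(donor)
    actin = np.empty_like(donor)
    v_px = _flow_px(params)
    for t in range(params.n_frames):
        m = masks[t].astype(float)
        beta = np.exp(-params.bleach_rate * t) if params.bleach else 1.0
        d_sig = params.background_signal + params.donor_level * m
        f_sig = params.background_signal + params.donor_level * ratio_true * beta * m
        if params.optics_blur_px > 0:
            d_sig = ndimage.gaussian_filter(d_sig, params.optics_blur_px)
            f_sig = ndimage.gaussian_filter(f_sig, params.optics_blur_px)
        donor[t] = _camera(d_sig, shading, params.dark_level, params.read_noise_sd, rng, params.noise)
        fret[t] = _camera(f_sig, shading, params.dark_level, params.read_noise_sd, rng, params.noise)
        # actin: advected speckle sampled from the static canvas (exact flow)
        off = texture.shape[0] // 2 - shape[0] // 2
        rows = np.arange(shape[0]) + off - v_px * t
        coords = np.meshgrid(rows, np.arange(shape[1]), indexing="ij")
        tex_t = ndimage.map_coordinates(texture, coords, order=1, mode="reflect")
        a_sig = params.background_signal + params.actin_level * (0.3 + tex_t) * m
        actin[t] = _camera(a_sig, shading, params.dark_level, params.read_noise_sd, rng, params.noise)

    truth = {
        "mask_series": masks,
        "force_field": force,
        "ratio_true": ratio_true,
        "bleach_rate": params.bleach_rate if params.bleach else 0.0,
        "flow_velocity_nm_s": params.flow_velocity_nm_s,
        "flow_px_per_frame": v_px,
        "shading": shading,
        "dark_level": params.dark_level,
        "events": mask_truth["events"],
        "seed": params.seed,
    }
    return SyntheticScene({"donor": donor, "fret": fret, "actin": actin}, truth, params)


def _flow_px(params: SceneParams) -> float:
    """Planted flow in px/frame along +row; negative nm/s moves toward +row.

    The retrograde sign convention is carried in ``flow_velocity_nm_s``;
    texture moves along the +row axis at the corresponding speed.
    """
    return abs(params.flow_velocity_nm_s) * params.frame_interval_s / params.pixel_size_nm


def make_zstack_scene(
    z_offset_truth: float,
    step: float = 25.0,
    n_planes: int = 41,
    mode: Literal["texture", "beads"] = "texture",
    chromatic_offset_nm: float = 0.0,
    shape: tuple[int, int] = (96, 96),
    sigma0_px: float = 1.0,
    blur_slope_px_per_nm: float = 0.006,
    signal_level: float = 1000.0,
    read_noise_sd: float = 2.0,
    noise: bool = True,
    n_beads: int = 12,
    seed: int = 0,
) -> SyntheticScene:
    """Two-channel TIRF z-stack with a planted axial offset between channels.

    Channel 2's in-focus plane sits at ``z_offset_truth + chromatic_offset_nm``
    relative to channel 1; defocus is modeled as Gaussian blur whose sigma
    grows with distance from focus, so in-plane variance peaks at focus.
    """
    rng = np.random.default_rng(seed)
    z = (np.arange(n_planes) - n_planes // 2) * float(step)
    zc1 = 0.0
    zc2 = z_offset_truth + chromatic_offset_nm
    if max(abs(zc1), abs(zc2)) > z.max() - 5 * step:
        raise ValueError("planted focus too close to the scan edge")

    def render(zc: float) -> np.ndarray:
        stack = np.empty((n_planes,) + shape)
        if mode == "texture":
            base = signal_level * (0.5 + _speckle_texture(shape, 1.0, np.random.default_rng(seed + 1)))
            for i, zi in enumerate(z):
                sig = np.hypot(sigma0_px, blur_slope_px_per_nm * (zi - zc))
                stack[i] = ndimage.gaussian_filter(base, sig)
        else:
            pr = np.random.default_rng(seed + 2)
            pos = pr.uniform(8, np.array(shape) - 8, size=(n_beads, 2))
            yy, xx = np.mgrid[: shape[0], : shape[1]]
            for i, zi in enumerate(z):
                sig = np.hypot(sigma0_px, blur_slope_px_per_nm * (zi - zc))
                img = np.zeros(shape)
                for (py, px) in pos:
                    img += np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sig**2)) / sig**2
                stack[i] = 20.0 + signal_level * img
        if noise:
            stack = rng.poisson(np.clip(stack, 0, None)).astype(float) + rng.normal(
                0, read_noise_sd, stack.shape
            )
        return stack

    ch1, ch2 = render(zc1), render(zc2)
    truth = {
        "z_positions": z,
        "z_center_ch1": zc1,
        "z_center_ch2": zc2,
        "z_offset": z_offset_truth,
        "chromatic_offset_nm": chromatic_offset_nm,
        "mode": mode,
    }
    return SyntheticScene({"ch1": ch1, "ch2": ch2}, truth)


def make_stain_scene(
    base_scene: SyntheticScene,
    rho: float,
    stain_level: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Add an antibody channel with a planted pixel correlation.

    The antibody image is a ``rho``-weighted mixture of the standardized
    inverted true-ratio image and white noise orthogonalized against it, so
    the realized in-mask Pearson correlation with the inverted ratio equals
    ``rho`` exactly before camera noise. ``truth['stain_rho']`` records rho.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    mask = base_scene.truth["mask_series"][0]
    inv = -base_scene.truth["ratio_true"]
    zin = inv[mask]
    sd = zin.std()
    z = (zin - zin.mean()) / (sd if sd > 0 else 1.0)
    g = rng.standard_normal(z.shape)
    if sd > 0:
        g = g - (g @ z) / (z @ z) * z  # orthogonalize: realized correlation == rho
    g = (g - g.mean()) / max(g.std(), 1e-12)
    ab_std = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * g
    ab = np.full(mask.shape, 30.0)
    ab[mask] = stain_level * (3.0 + ab_std)
    if noise_sd > 0:
        ab = ab + rng.normal(0, noise_sd, ab.shape)
    channels = dict(base_scene.channels)
    channels["antibody"] = ab[None] if base_scene.channels["donor"].ndim == 3 else ab
    truth = dict(base_scene.truth)
    truth["stain_rho"] = rho
    return SyntheticScene(channels, truth, base_scene.params)


def make_calibration_table(
    n: int = 13,
    noise_sd: float = 0.0,
    seed: int = 0,
    coeffs: np.ndarray = DEFAULT_TRUTH_COEFFS,
    domain: tuple[float, float] = (0.0, 6.0),
) -> tuple[list[CalibPoint], np.ndarray]:
    """Sample (force, efficiency) calibration points from a known quartic.

    Returns (points, truth coefficients). With ``noise_sd == 0`` a quartic
    refit recovers ``coeffs`` to numerical precision.
    """
    if n < 5:
        raise ValueError("need n >= 5 calibration points")
    rng = np.random.default_rng(seed)
    f = np.linspace(domain[0], domain[1], n)
    e = np.polynomial.polynomial.polyval(f, coeffs)
    if noise_sd > 0:
        e = e + rng.normal(0, noise_sd, n)
    e = np.clip(e, 1e-3, 1 - 1e-3)
    return [CalibPoint(fi, ei) for fi, ei in zip(f, e)], np.asarray(coeffs).copy()
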