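"""Reading and writing pipeline artifacts.

Stacks travel as (OME-)TIFF via tifffile; tables as CSV; models, truth
sidecars and run manifests as JSON. Force/ratio maps are written as
32-bit float TIFF with invalid pixels as NaN. The inverted-heat-map PNG
rendering (low ratio / high force = hot) uses fixed, configurable color
limits so frames and cells are directly comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "write_stack",
    "read_stack",
    "write_map_series",
    "save_scene",
    "load_scene",
    "render_inverted_heatmap",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(path: str | Path, stack: np.ndarray, axes: str = "TYX", **meta) -> None:
    """Write a stack as OME-TIFF with axis metadata."""
    tifffile.imwrite(
        str(path),
        np.asarray(stack, dtype=np.float32),
        ome=True,
        metadata={"axes": axes, **meta},
    )


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_map_series(path: str | Path, maps) -> None:
    """Write RatioMap/ForceMap frames as a float32 TIFF with NaN = invalid."""
    stack = np.stack([m.masked() for m in maps]).astype(np.float32)
    write_stack(path, stack)


def save_scene(scene, directory: str | Path) -> Path:
    """Write a synthetic scene: one OME-TIFF per channel, truth sidecar, manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, stack in scene.channels.items():
        fn = f"{name}.ome.tif"
        axes = "TYX" if stack.ndim == 3 else "YX"
        write_stack(d / fn, stack, axes=axes)
        files[name] = fn
    truth = _jsonable(scene.truth)
    (d / "truth.json").write_text(json.dumps(truth, indent=1))
    manifest = {"channels": files, "truth": "truth.json"}
    if scene.params is not None:
        from dataclasses import asdict, is_dataclass

        if is_dataclass(scene.params):
            manifest["params"] = _jsonable(asdict(scene.params))
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return d


def load_scene(directory: str | Path):
    """Load a scene directory written by :func:`save_scene`."""
    from .synth import SyntheticScene

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    channels = {k: read_stack(d / fn) for k, fn in manifest["channels"].items()}
    truth = json.loads((d / "truth.json").read_text())
    for key in ("mask_series", "force_field", "ratio_true", "shading"):
        if key in truth:
            truth[key] = np.asarray(truth[key])
    if "mask_series" in truth:
        truth["mask_series"] = truth["mask_series"].astype(bool)
    return SyntheticScene(channels, truth)


def render_inverted_heatmap(
    ratio: np.ndarray,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "jet_r",
) -> None:
    """PNG of a ratio map with an inverted heat map (low ratio = hot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5), dpi=120)
    im = ax.imshow(ratio, cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, fraction=0.045, label="FRET ratio")
    fig.savefig(str(path), bbox_inches="tight")
    plt.close(fig)
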