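"""Per-pixel map containers shared across the pipeline.

A :class:`RatioMap` holds the per-pixel FRET ratio (acceptor emission under
donor excitation divided by donor emission) together with a validity mask;
a :class:`ForceMap` holds the calibrated per-pixel force in piconewtons.
Invalid pixels are carried explicitly rather than encoded as sentinel
values so that downstream statistics never mix signal with background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RatioMap", "ForceMap"]


@dataclass
class RatioMap:
    """Per-pixel FRET ratio with validity mask.

    Parameters
    ----------
    ratio : ndarray of float
        FRET-channel / donor-channel per pixel. Values at invalid pixels
        are unspecified (typically NaN).
    valid : ndarray of bool
        True where both channels passed the inclusion threshold.
    frame : int
        Frame index within the movie this map was computed from.
    bg : Any
        Background statistics used for thresholding (bookkeeping only).
    """

    ratio: np.ndarray
    valid: np.ndarray
    frame: int = 0
    bg: Any = None

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ratio.shape != self.valid.shape:
            raise ValueError("ratio and valid mask shapes differ")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ratio.shape

    def masked(self) -> np.ndarray:
        """Ratio with invalid pixels set to NaN."""
        out = self.ratio.astype(float).copy()
        out[~self.valid] = np.nan
        return out


@dataclass
class ForceMap:
    """Per-pixel force in piconewtons derived from a :class:`RatioMap`.

    ``saturated`` marks pixels whose ratio fell outside the calibrated
    ratio domain and were clamped to the nearest force endpoint.
    """

    force: np.ndarray
    valid: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame: int = 0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.saturated is None:
            self.saturated = np.zeros_like(self.valid)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if self.force.shape != self.valid.shape:
            raise ValueError("force and valid mask shapes differ")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.force.shape

    def masked(self) -> np.ndarray:
        """Force with invalid pixels set to NaN."""
        out = self.force.astype(float).copy()
        out[~self.valid] = np.nan
        return out
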