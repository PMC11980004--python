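"""Core containers shared across the pipeline.

A short-axis LGE slice enters the pipeline as a :class:`SliceROI`: the raw
pixel grid, a boolean myocardium mask of the same shape, and the in-plane
pixel spacing in millimetres.  After spatial standardization, intensity
normalization and gray-level discretization it becomes a
:class:`QuantizedROI`, the input to every texture-matrix builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SliceROI", "QuantizedROI", "DegenerateSliceError"]


class DegenerateSliceError(ValueError):
    """Raised when a slice cannot support the requested texture statistic.

    Typical causes: an empty mask, or a mask so small that no pair of
    neighbouring pixels is fully inside it.
    """


@dataclass
class SliceROI:
    """One 2D grayscale slice with its region-of-interest mask.

    Parameters
    ----------
    pixels
        2D float array of signal intensities (arbitrary units).
    mask
        2D boolean array, same shape as ``pixels``; True marks myocardium.
    spacing_mm
        (row, column) pixel spacing in millimetres.
    """

    pixels: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        sr, sc = self.spacing_mm
        if not (sr > 0 and sc > 0):
            raise ValueError(f"pixel spacing must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(sr), float(sc))

    @property
    def masked_values(self) -> np.ndarray:
        """1D array of pixel values inside the mask."""
        return self.pixels[self.mask]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "SliceROI":
        return SliceROI(self.pixels.copy(), self.mask.copy(), self.spacing_mm)


@dataclass
class QuantizedROI:
    """Gray-level discretized ROI.

    ``levels`` holds integer gray levels in ``1..n_levels`` on masked pixels
    and 0 elsewhere; texture matrices index levels from 1 as is conventional.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("masked levels must lie in [1, n_levels]")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def occupied_levels(self) -> np.ndarray:
        return np.unique(self.levels[self.mask])
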