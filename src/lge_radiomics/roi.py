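"""ROI standardization: spatial resampling, intensity normalization,
gray-level quantization, and scar (LGE) quantification.

Every slice is brought to a common 1x1 mm grid by bilinear interpolation
(nearest-neighbour for the mask, which must stay boolean), its masked
intensities are min-max normalized to [0, 1], and the normalized values are
discretized into a fixed number of equal-width gray-level bins.  Scar burden
uses the clinical 5-SD rule: a myocardial pixel counts as enhanced when its
intensity exceeds mean + 5*SD of a reference region of visually normal
myocardium.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import QuantizedROI, SliceROI

__all__ = [
    "resample_to_unit_spacing",
    "minmax_normalize",
    "quantize",
    "lge_burden",
    "DEFAULT_N_LEVELS",
    "SD_THRESHOLD_FACTOR",
]

#: default number of gray-level bins used by the texture stage
DEFAULT_N_LEVELS = 32

#: scar threshold = mean(normal) + SD_THRESHOLD_FACTOR * SD(normal)
SD_THRESHOLD_FACTOR = 5.0


def resample_to_unit_spacing(roi: SliceROI) -> SliceROI:
    """Resample a slice to 1x1 mm pixel spacing.

    Pixels are interpolated bilinearly on a grid whose points sit at integer
    millimetre positions of the input's physical frame (pixel centres at
    ``index * spacing``); input grid points that coincide with output grid
    points keep their values exactly.  The mask is resampled with
    nearest-neighbour interpolation so it remains boolean.  Positions beyond
    the last input pixel centre are edge-extended.

    A slice already at 1x1 mm is returned as an identical copy.
    """
    sr, sc = roi.spacing_mm
    if sr <= 0 or sc <= 0:
        raise ValueError("spacing must be positive")
    if sr == 1.0 and sc == 1.0:
        return roi.copy()
    n_r, n_c = roi.pixels.shape
    out_r = max(int(round(n_r * sr)), 1)
    out_c = max(int(round(n_c * sc)), 1)
    rr = np.arange(out_r, dtype=float) / sr
    cc = np.arange(out_c, dtype=float) / sc
    coords = np.meshgrid(rr, cc, indexing="ij")
    pixels = ndimage.map_coordinates(roi.pixels, coords, order=1, mode="nearest")
    mask = ndimage.map_coordinates(
        roi.mask.astype(np.uint8), coords, order=0, mode="nearest"
    ).astype(bool)
    return SliceROI(pixels, mask, (1.0, 1.0))


def minmax_normalize(roi: SliceROI, bounds: tuple[float, float] | None = None) -> SliceROI:
    """Min-max normalize intensities over the mask to the range [0, 1].

    The minimum and maximum are computed over masked pixels only, unless
    explicit ``bounds`` are supplied (used for per-patient-stack
    normalization, where all slices share one intensity range; values are
    clipped to the bounds first).  Pixels outside the mask are set to 0 and
    carry no meaning downstream.  A constant ROI (max == min) maps to all
    zeros rather than raising: such degenerate slices then take their
    constant-image texture values.
    """
    if roi.n_masked == 0:
        raise ValueError("cannot normalize an empty mask")
    vals = roi.masked_values
    if bounds is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
        vals = np.clip(vals, lo, hi)
    out = np.zeros_like(roi.pixels)
    if hi > lo:
        out[roi.mask] = (vals - lo) / (hi - lo)
    return SliceROI(out, roi.mask.copy(), roi.spacing_mm)


def quantize(roi: SliceROI, n_levels: int = DEFAULT_N_LEVELS) -> QuantizedROI:
    """Discretize a [0, 1]-normalized ROI into equal-width gray-level bins.

    ``level = min(floor(x * n_levels) + 1, n_levels)`` so 0 maps to level 1
    and 1 maps to level ``n_levels``.  Quantization is monotone in x.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = roi.masked_values
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError("quantize expects values in [0, 1]; normalize first")
    levels = np.zeros(roi.pixels.shape, dtype=np.int64)
    levels[roi.mask] = np.minimum(
        np.floor(vals * n_levels).astype(np.int64) + 1, n_levels
    )
    return QuantizedROI(levels, roi.mask.copy(), n_levels)


def lge_burden(
    slices: list[SliceROI],
    normal_masks: list[np.ndarray],
    sd_factor: float = SD_THRESHOLD_FACTOR,
) -> tuple[bool, float]:
    """Scar presence and burden by the SD-threshold rule, pooled over slices.

    Parameters
    ----------
    slices
        The patient's myocardium slices (raw intensities, any spacing).
    normal_masks
        Per-slice boolean masks marking reference normal myocardium; each
        must be a nonempty subset of the corresponding myocardium mask.
        Reference pixels are pooled across slices to one threshold.
    sd_factor
        Number of SDs above the normal-myocardium mean; 5 by default.

    Returns
    -------
    (presence, burden)
        ``burden`` is the percentage of myocardial pixels above the
        threshold, pooled over all slices (an area proxy for the clinical
        %-of-LV-mass quantity); ``presence`` is ``burden > 0``.
    """
    if len(slices) != len(normal_masks):
        raise ValueError("need one normal mask per slice")
    normal_vals = []
    for roi, nmask in zip(slices, normal_masks):
        nmask = np.asarray(nmask, dtype=bool)
        if nmask.shape != roi.mask.shape:
            raise ValueError("normal mask shape mismatch")
        if np.any(nmask & ~roi.mask):
            raise ValueError("normal ROI must lie inside the myocardium mask")
        normal_vals.append(roi.pixels[nmask])
    normal_vals = np.concatenate(normal_vals) if normal_vals else np.array([])
    if normal_vals.size == 0:
        raise ValueError("empty normal-myocardium reference ROI")
    threshold = float(normal_vals.mean()) + sd_factor * float(normal_vals.std())
    n_myo = 0
    n_hyper = 0
    for roi in slices:
        vals = roi.masked_values
        n_myo += vals.size
        n_hyper += int((vals > threshold).sum())
    if n_myo == 0:
        raise ValueError("no myocardial pixels")
    burden = 100.0 * n_hyper / n_myo
    return burden > 0.0, burden
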