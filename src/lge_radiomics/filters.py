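"""Image filter bank applied to each normalized ROI before feature extraction.

Besides the original image, ten filtered versions are produced: four
elementwise transforms (exponential, logarithm, square, square root), a
gradient-magnitude image, a rotation-invariant uniform local binary pattern
image, and the four subbands (LL, LH, HL, HH) of a one-level 2D wavelet
decomposition.  Each filtered image is re-min-max-normalized over the mask so
the same gray-level quantizer applies to every image type.

Neighbourhood filters (gradient, LBP, wavelet) need values outside the mask;
those pixels are filled with the masked mean first so ROI-border responses
are not contaminated by the zero background.  Pixels outside the mask are
excluded from all downstream statistics regardless.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable

import numpy as np
import pywt
from skimage.feature import local_binary_pattern

from .core import SliceROI
from .roi import minmax_normalize

__all__ = ["IMAGE_TYPES", "apply_filter_bank", "gradient_magnitude", "wavelet_subbands"]

#: fixed image-type names used as feature-name prefixes
IMAGE_TYPES = (
    "original",
    "exponential",
    "gradient",
    "logarithm",
    "square",
    "squareroot",
    "lbp",
    "wavelet-LL",
    "wavelet-LH",
    "wavelet-HL",
    "wavelet-HH",
)

#: elementwise transforms; log uses ln(1+x) to stay finite at 0
ELEMENTWISE: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "exponential": np.exp,
    "logarithm": np.log1p,
    "square": np.square,
    "squareroot": np.sqrt,
}

LBP_RADIUS = 1
LBP_POINTS = 8
WAVELET = "haar"


def gradient_magnitude(pixels: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude (unit pixel spacing)."""
    gy, gx = np.gradient(pixels)
    return np.hypot(gy, gx)


def wavelet_subbands(pixels: np.ndarray, wavelet: str = WAVELET) -> dict[str, np.ndarray]:
    """One-level 2D separable wavelet decomposition, upsampled to input shape.

    Subbands are nearest-neighbour upsampled by 2 in each axis and cropped,
    so all four outputs align with the input grid.
    """
    ll, (lh, hl, hh) = pywt.dwt2(pixels, wavelet, mode="periodization")
    out = {}
    for name, band in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
        up = np.repeat(np.repeat(band, 2, axis=0), 2, axis=1)
        out[name] = up[: pixels.shape[0], : pixels.shape[1]]
    return out


def _mean_filled(roi: SliceROI) -> np.ndarray:
    filled = np.full_like(roi.pixels, float(roi.masked_values.mean()))
    filled[roi.mask] = roi.pixels[roi.mask]
    return filled


def apply_filter_bank(roi: SliceROI, renormalize: bool = True) -> dict[str, SliceROI]:
    """Compute the original plus 10 filtered versions of a normalized slice.

    Parameters
    ----------
    roi
        A [0, 1]-normalized slice (see :func:`lge_radiomics.roi.minmax_normalize`).
    renormalize
        Re-min-max-normalize each filtered image over the mask (default); when
        False the raw filter responses are returned.

    Returns
    -------
    dict mapping each name in :data:`IMAGE_TYPES` to a SliceROI sharing the
    input mask.
    """
    vals = roi.masked_values
    if vals.size == 0:
        raise ValueError("empty mask")
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("filter bank expects a [0, 1]-normalized ROI")

    out: dict[str, SliceROI] = {"original": roi.copy()}
    for name, fn in ELEMENTWISE.items():
        img = np.zeros_like(roi.pixels)
        img[roi.mask] = fn(vals)
        out[name] = SliceROI(img, roi.mask.copy(), roi.spacing_mm)

    filled = _mean_filled(roi)
    out["gradient"] = SliceROI(gradient_magnitude(filled), roi.mask.copy(), roi.spacing_mm)
    with warnings.catch_warnings():
        # float input is intended; ties at machine precision are irrelevant here
        warnings.simplefilter("ignore", UserWarning)
        lbp = local_binary_pattern(filled, LBP_POINTS, LBP_RADIUS, method="uniform")
    out["lbp"] = SliceROI(lbp.astype(float), roi.mask.copy(), roi.spacing_mm)
    for band, img in wavelet_subbands(filled).items():
        out[f"wavelet-{band}"] = SliceROI(img, roi.mask.copy(), roi.spacing_mm)

    if renormalize:
        # the original is normalized by precondition; re-normalizing it here
        # would undo shared per-stack intensity bounds
        out = {
            name: (s if name == "original" else minmax_normalize(s))
            for name, s in out.items()
        }
    return out
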