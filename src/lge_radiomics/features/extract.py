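"""Per-slice and per-patient radiomic feature extraction.

The pipeline for one slice: resample to 1x1 mm -> min-max normalize over the
myocardium mask -> apply the 11-image filter bank -> quantize each image type
-> compute the six feature families.  Feature names follow the
``imageType_family_Feature`` convention (e.g. ``original_glcm_Autocorrelation``).
A patient's feature vector is the unweighted mean over their non-degenerate
slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import DegenerateSliceError, SliceROI
from ..filters import IMAGE_TYPES, apply_filter_bank
from ..roi import DEFAULT_N_LEVELS, minmax_normalize, quantize, resample_to_unit_spacing
from . import families, matrices

__all__ = [
    "ExtractionConfig",
    "FEATURE_FAMILIES",
    "extract_slice_features",
    "extract_patient_features",
    "extract_cohort_features",
]

logger = logging.getLogger(__name__)

FEATURE_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass
class ExtractionConfig:
    """Knobs of the extraction stage.

    n_levels
        Gray-level bin count for quantization (default 32).
    image_types / families
        Subsets of :data:`IMAGE_TYPES` / :data:`FEATURE_FAMILIES` to compute.
    renormalize_filtered
        Re-min-max-normalize filtered images before quantization (default).
    """

    n_levels: int = DEFAULT_N_LEVELS
    image_types: tuple[str, ...] = IMAGE_TYPES
    families: tuple[str, ...] = FEATURE_FAMILIES
    renormalize_filtered: bool = True
    normalization: str = "slice"  # "slice": per-slice min-max; "stack": per-patient

    def __post_init__(self) -> None:
        unknown = set(self.image_types) - set(IMAGE_TYPES)
        if unknown:
            raise ValueError(f"unknown image types: {sorted(unknown)}")
        unknown = set(self.families) - set(FEATURE_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.normalization not in ("slice", "stack"):
            raise ValueError("normalization must be 'slice' or 'stack'")


def _family_features(roi: SliceROI, config: ExtractionConfig) -> dict[str, float]:
    q = quantize(roi, config.n_levels)
    out: dict[str, float] = {}
    if "firstorder" in config.families:
        for k, v in families.firstorder_features(roi.masked_values, q).items():
            out[f"firstorder_{k}"] = v
    if "glcm" in config.families:
        for k, v in families.glcm_features(matrices.glcm(q)).items():
            out[f"glcm_{k}"] = v
    if "glrlm" in config.families:
        for k, v in families.glrlm_features(matrices.glrlm(q)).items():
            out[f"glrlm_{k}"] = v
    if "glszm" in config.families:
        for k, v in families.glszm_features(matrices.glszm(q)).items():
            out[f"glszm_{k}"] = v
    if "gldm" in config.families:
        for k, v in families.gldm_features(matrices.gldm(q)).items():
            out[f"gldm_{k}"] = v
    if "ngtdm" in config.families:
        for k, v in families.ngtdm_features(matrices.ngtdm(q)).items():
            out[f"ngtdm_{k}"] = v
    return out


def extract_slice_features(
    roi: SliceROI,
    config: ExtractionConfig | None = None,
    intensity_bounds: tuple[float, float] | None = None,
) -> dict[str, float]:
    """All features of one slice, keyed ``imageType_family_Feature``.

    ``intensity_bounds`` overrides the per-slice min/max (per-stack
    normalization).  Raises :class:`DegenerateSliceError` when the mask
    cannot support the texture matrices (no valid neighbour pair).
    """
    config = config or ExtractionConfig()
    std = minmax_normalize(resample_to_unit_spacing(roi), bounds=intensity_bounds)
    bank = apply_filter_bank(std, renormalize=config.renormalize_filtered)
    out: dict[str, float] = {}
    for image_type in config.image_types:
        for name, value in _family_features(bank[image_type], config).items():
            out[f"{image_type}_{name}"] = value
    return out


def extract_patient_features(
    slices: list[SliceROI], config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Mean feature vector across a patient's non-degenerate slices."""
    config = config or ExtractionConfig()
    bounds = None
    if config.normalization == "stack" and slices:
        pooled = np.concatenate([s.masked_values for s in slices])
        bounds = (float(pooled.min()), float(pooled.max()))
    rows = []
    for idx, roi in enumerate(slices):
        try:
            rows.append(extract_slice_features(roi, config, intensity_bounds=bounds))
        except DegenerateSliceError as exc:
            logger.warning("slice %d skipped as degenerate: %s", idx, exc)
    if not rows:
        raise DegenerateSliceError("patient excluded: all slices degenerate")
    names = rows[0].keys()
    return {name: float(np.mean([r[name] for r in rows])) for name in names}


def extract_cohort_features(
    patients: dict[str, list[SliceROI]], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per patient id, one column per
    feature.  Patients whose slices are all degenerate are dropped (logged)."""
    config = config or ExtractionConfig()
    records = {}
    for pid, slices in patients.items():
        try:
            records[pid] = extract_patient_features(slices, config)
        except DegenerateSliceError:
            logger.warning("patient %s excluded: all slices degenerate", pid)
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "patient_id"
    return df
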