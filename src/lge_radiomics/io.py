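"""Readers and writers for image stacks and cohort tables.

Supported on-disk forms:

* NIfTI volumes (one file per patient; slices along the last axis) with a
  matching mask volume, read via nibabel; pixel spacing from the affine.
* DICOM series directories read via pydicom (PixelSpacing from metadata).
* A plain ``.npz`` exchange container used for synthetic fixtures: arrays
  ``pixels`` (slices, rows, cols), ``mask``, optional ``scar``, and
  ``spacing`` (2,).
* Cohort covariate/outcome tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import SliceROI
from .synthetic import Cohort

__all__ = [
    "load_nifti_stack",
    "load_dicom_series",
    "save_patient_npz",
    "load_patient_npz",
    "save_cohort",
    "load_cohort_table",
]


def load_nifti_stack(
    image_path: str | Path,
    mask_path: str | Path,
    spacing_override: tuple[float, float] | None = None,
) -> list[SliceROI]:
    """Read a NIfTI image volume and mask volume into a list of slices."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    pixels = np.asarray(img.get_fdata(), dtype=float)
    mask = np.asarray(msk.get_fdata()) > 0.5
    if pixels.shape != mask.shape:
        raise ValueError("image and mask volumes have different shapes")
    if pixels.ndim == 2:
        pixels, mask = pixels[..., None], mask[..., None]
    zooms = img.header.get_zooms()[:2]
    spacing = spacing_override or (float(zooms[0]), float(zooms[1]))
    return [
        SliceROI(pixels[:, :, k], mask[:, :, k], spacing)
        for k in range(pixels.shape[2])
        if mask[:, :, k].any()
    ]


def load_dicom_series(
    directory: str | Path,
    masks: list[np.ndarray],
    spacing_override: tuple[float, float] | None = None,
) -> list[SliceROI]:
    """Read a DICOM series (sorted by InstanceNumber) with external masks."""
    import pydicom

    files = sorted(
        Path(directory).glob("*.dcm"),
        key=lambda f: int(getattr(pydicom.dcmread(f, stop_before_pixels=True), "InstanceNumber", 0)),
    )
    if len(files) != len(masks):
        raise ValueError("need one mask per DICOM slice")
    out = []
    for f, mask in zip(files, masks):
        ds = pydicom.dcmread(f)
        spacing = spacing_override or tuple(float(v) for v in ds.PixelSpacing)
        out.append(SliceROI(ds.pixel_array.astype(float), mask, spacing))
    return out


def save_patient_npz(path: str | Path, slices: list[SliceROI], scar_masks=None) -> None:
    """Write one patient's stack to the plain-array exchange container."""
    arrays = {
        "pixels": np.stack([s.pixels for s in slices]),
        "mask": np.stack([s.mask for s in slices]),
        "spacing": np.asarray(slices[0].spacing_mm),
    }
    if scar_masks is not None:
        arrays["scar"] = np.stack(scar_masks)
    np.savez_compressed(str(path), **arrays)


def load_patient_npz(path: str | Path) -> tuple[list[SliceROI], np.ndarray | None]:
    data = np.load(str(path))
    spacing = tuple(data["spacing"])
    slices = [
        SliceROI(p, m, spacing) for p, m in zip(data["pixels"], data["mask"])
    ]
    scar = data["scar"] if "scar" in data else None
    return slices, scar


def save_cohort(cohort: Cohort, out_dir: str | Path, images: bool = True) -> Path:
    """Write a synthetic cohort: cohort.csv plus per-patient npz stacks."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out_dir / "cohort.csv", index=False)
    if images:
        img_dir = out_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for p in cohort.patients:
            save_patient_npz(img_dir / f"{p.patient_id}.npz", p.slices, p.scar_masks)
    return out_dir / "cohort.csv"


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
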