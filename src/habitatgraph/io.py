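"""Readers and writers: NIfTI / PNG slices, cohort manifests, feature tables.

Phantoms and real data alike are exchanged as per-sequence image + mask files.
NIfTI files carry pixel spacing in the header; for PNG (16-bit grayscale) the
spacing must be supplied by configuration. 3D NIfTI volumes are reduced to the
2D slice with the maximum in-mask area (ties: lowest index) or to an explicit
slice index.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ParameterError
from .habitats import SlicePair

__all__ = [
    "write_phantom",
    "write_cohort",
    "read_subject",
    "select_slice",
]

_SUBJECT_KEYS = ("t1c", "flair", "roi_t1", "roi_flair")


def _is_nifti(path: str | Path) -> bool:
    name = str(path)
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _write_image(path: Path, data: np.ndarray, spacing_mm: tuple[float, float]) -> None:
    if _is_nifti(path):
        affine = np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
        img.header.set_zooms((spacing_mm[0], spacing_mm[1]))
        nib.save(img, str(path))
    else:
        arr = np.asarray(data)
        if arr.dtype == bool:
            iio.imwrite(path, arr.astype(np.uint8) * 255)
        else:
            iio.imwrite(path, np.clip(np.round(arr), 0, 65535).astype(np.uint16))


def _read_image(path: Path) -> tuple[np.ndarray, tuple[float, float] | None]:
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        zooms = img.header.get_zooms()
        return data, (float(zooms[0]), float(zooms[1]))
    return np.asarray(iio.imread(path)).astype(float), None


def write_phantom(
    slices: SlicePair, out_dir: str | Path, fmt: str = "nifti"
) -> dict:
    """Write one subject's four files; returns a path mapping."""
    if fmt not in ("nifti", "png"):
        raise ParameterError(f"unknown format {fmt!r}")
    ext = ".nii.gz" if fmt == "nifti" else ".png"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = slices.subject_id
    paths = {}
    for key, data in (
        ("t1c", slices.t1c),
        ("flair", slices.flair),
        ("roi_t1", slices.roi_t1),
        ("roi_flair", slices.roi_flair),
    ):
        path = out_dir / f"{sid}_{key}{ext}"
        _write_image(path, data, slices.spacing_mm)
        paths[key] = str(path)
    return paths


def write_cohort(
    cohort: list[tuple[SlicePair, int]], out_dir: str | Path, fmt: str = "nifti"
) -> Path:
    """Write a cohort to disk plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for slices, label in cohort:
        paths = write_phantom(slices, out_dir, fmt=fmt)
        rows.append({"subject_id": slices.subject_id, **paths, "label": label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def select_slice(mask_volume: np.ndarray, rule: str | int = "max-area") -> int:
    """Slice index for a 3D mask volume (slices along the last axis).

    ``"max-area"`` picks the slice with the most in-mask pixels, ties going to
    the lowest index; an integer selects that slice directly.
    """
    if isinstance(rule, (int, np.integer)):
        idx = int(rule)
        if not 0 <= idx < mask_volume.shape[-1]:
            raise ParameterError(f"slice index {idx} out of range")
        return idx
    if rule != "max-area":
        raise ParameterError(f"unknown slice selection rule {rule!r}")
    areas = mask_volume.reshape(-1, mask_volume.shape[-1]).sum(axis=0)
    return int(np.argmax(areas))  # argmax returns the first (lowest) maximum


def read_subject(
    paths: dict,
    spacing_mm: tuple[float, float] | None = None,
    slice_selection: str | int = "max-area",
    subject_id: str | None = None,
) -> SlicePair:
    """Load one subject from image + mask files.

    ``paths`` maps the keys t1c, flair, roi_t1, roi_flair to file paths.
    For 3D NIfTI input, the T1 ROI volume chooses the slice (per
    ``slice_selection``) and the same index is used for every volume, the two
    sequences being assumed co-registered. Pixel spacing comes from the NIfTI
    header unless overridden.
    """
    missing = [k for k in _SUBJECT_KEYS if k not in paths]
    if missing:
        raise ParameterError(f"missing subject file keys: {missing}")
    for key in _SUBJECT_KEYS:
        if not os.path.exists(str(paths[key])):
            raise ParameterError(f"file not found for {key}: {paths[key]}")
    data: dict = {}
    header_spacing = None
    for key in _SUBJECT_KEYS:
        arr, sp = _read_image(Path(paths[key]))
        data[key] = arr
        if sp is not None and header_spacing is None:
            header_spacing = sp
    shapes = {data[k].shape for k in _SUBJECT_KEYS}
    if len(shapes) != 1:
        raise ParameterError(f"image/mask shape mismatch: {sorted(shapes)}")
    if data["roi_t1"].ndim == 3:
        idx = select_slice(data["roi_t1"] > 0, slice_selection)
        data = {k: v[..., idx] for k, v in data.items()}
    elif data["roi_t1"].ndim != 2:
        raise ParameterError("expected 2D images or 3D volumes")
    roi_t1 = data["roi_t1"] > 0
    roi_flair = data["roi_flair"] > 0
    if not roi_t1.any():
        raise ParameterError("T1 ROI mask is empty")
    if not roi_flair.any():
        raise ParameterError("FLAIR ROI mask is empty")
    spacing = spacing_mm or header_spacing or (1.0, 1.0)
    return SlicePair(
        t1c=data["t1c"],
        flair=data["flair"],
        roi_t1=roi_t1,
        roi_flair=roi_flair,
        spacing_mm=tuple(float(s) for s in spacing),
        subject_id=subject_id or "subject",
    )
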