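"""Reading and writing of pipeline artifacts.

Image series are stored as uncompressed 4-D NIfTI-1 volumes (x=column,
y=row, z=slice, t=time; pixdim in mm) with a YAML sidecar holding the
acquisition schedule; label and class volumes as 3-D integer NIfTI-1 plus a
JSON code table; parametric maps as NIfTI-1 value/mask pairs with a CSV
diagnostics summary; fraction reports as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import yaml

from .containers import AcquisitionSchedule, ImageSeries, ParametricMap


def _affine(pixel_um: float, slice_mm: float) -> np.ndarray:
    return np.diag([pixel_um / 1000.0, pixel_um / 1000.0, slice_mm, 1.0])


def _to_xyz(data: np.ndarray) -> np.ndarray:
    # internal (slice, row, col[, t]) -> NIfTI (x=col, y=row, z=slice[, t])
    axes = (2, 1, 0) + tuple(range(3, data.ndim))
    return np.ascontiguousarray(np.transpose(data, axes))


def _from_xyz(data: np.ndarray) -> np.ndarray:
    axes = (2, 1, 0) + tuple(range(3, data.ndim))
    return np.ascontiguousarray(np.transpose(data, axes))


def write_series(series: ImageSeries, path) -> Tuple[Path, Path]:
    """Write an image series as .nii plus a YAML schedule sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(_to_xyz(series.data), _affine(series.pixel_um,
                                                        series.slice_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"schedule": series.schedule.to_dict(),
             "pixel_um": float(series.pixel_um),
             "slice_mm": float(series.slice_mm),
             "provenance": series.provenance},
            fh, sort_keys=True)
    return path, sidecar


def read_series(path) -> ImageSeries:
    path = Path(path)
    img = nib.load(str(path))
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    return ImageSeries(
        data=_from_xyz(np.asarray(img.dataobj, dtype=float)),
        schedule=AcquisitionSchedule.from_dict(meta["schedule"]),
        pixel_um=float(meta["pixel_um"]),
        slice_mm=float(meta["slice_mm"]),
        provenance=meta.get("provenance", ""),
    )


def write_labels(labels_array: np.ndarray, code_table: dict, path,
                 cell_um: float, slice_mm: float) -> Tuple[Path, Path]:
    """Write an integer label volume plus its JSON code table."""
    path = Path(path)
    img = nib.Nifti1Image(_to_xyz(labels_array.astype(np.uint8)),
                          _affine(cell_um, slice_mm))
    nib.save(img, str(path))
    table = path.with_suffix(".json")
    with open(table, "w") as fh:
        json.dump({str(k): v for k, v in code_table.items()}, fh, indent=1,
                  sort_keys=True)
    return path, table


def write_map(pmap: ParametricMap, path) -> Path:
    """Write a parametric map (values, with mask as a companion volume)."""
    path = Path(path)
    affine = _affine(pmap.pixel_um or 1.0, pmap.slice_mm or 1.0)
    nib.save(nib.Nifti1Image(_to_xyz(pmap.values), affine), str(path))
    mask_path = path.with_name(path.stem + "_mask.nii")
    nib.save(nib.Nifti1Image(_to_xyz(pmap.mask.astype(np.uint8)), affine),
             str(mask_path))
    return path


def read_map(path, unit: str = "") -> ParametricMap:
    path = Path(path)
    vals = _from_xyz(np.asarray(nib.load(str(path)).dataobj, dtype=float))
    mask_path = path.with_name(path.stem + "_mask.nii")
    mask = _from_xyz(np.asarray(nib.load(str(mask_path)).dataobj)) > 0
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return ParametricMap(values=vals, mask=mask, unit=unit,
                         pixel_um=float(zooms[0]) * 1000.0,
                         slice_mm=float(zooms[2]))


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
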