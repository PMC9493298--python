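"""NIfTI and CSV interchange for SUV volumes, VOI masks and parameter tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .pet_metrics import SuvVolume, TumorParameters, Voi


def read_suv_nifti(path: str | Path) -> SuvVolume:
    """Load an SUV volume from NIfTI-1; spacing comes from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SuvVolume(values=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _affine(volume: SuvVolume) -> np.ndarray:
    aff = np.diag(list(volume.spacing) + [1.0])
    aff[:3, 3] = volume.origin
    return aff


def write_suv_nifti(volume: SuvVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_voi_nifti(voi: Voi, volume: SuvVolume, path: str | Path) -> None:
    """Write a VOI mask with the geometry of its source volume."""
    img = nib.Nifti1Image(voi.mask.astype(np.uint8), _affine(volume))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def parameters_to_frame(
    parameters: list[TumorParameters], ids: list | None = None
) -> pd.DataFrame:
    """Tabulate per-tumor parameter sets with canonical column names."""
    frame = pd.DataFrame([p.as_row() for p in parameters], columns=TumorParameters.CSV_COLUMNS)
    if ids is not None:
        frame.insert(0, "id", ids)
    return frame


def write_parameters_csv(
    parameters: list[TumorParameters], path: str | Path, ids: list | None = None
) -> None:
    parameters_to_frame(parameters, ids=ids).to_csv(path, index=False)
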