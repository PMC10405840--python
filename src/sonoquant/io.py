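"""Reading and writing the standard on-disk formats.

MR and PET volumes travel as NIfTI-1 (spacing in the header), confocal
fields as multi-page TIFF (one page per channel), ground truth and reports
as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .core import RasterVolume
from .synthetic import GroundTruth

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_tiff_stack",
    "write_tiff_stack",
    "write_ground_truth",
    "read_ground_truth",
]


def read_nifti(path) -> RasterVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RasterVolume(np.asarray(img.dataobj, dtype=float), spacing)


def write_nifti(vol: RasterVolume, path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def read_tiff_stack(path, pixel_size: float) -> RasterVolume:
    """Multi-page TIFF as a (channels, y, x) RasterVolume."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return RasterVolume(data.astype(float), (pixel_size, pixel_size), channel_axis=0)


def write_tiff_stack(vol: RasterVolume, path) -> None:
    data = vol.data if vol.channel_axis is not None else vol.data[None]
    tifffile.imwrite(str(path), data.astype(np.float32))


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
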