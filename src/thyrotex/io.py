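"""Raster and table I/O.

Slice images and ADC maps are exchanged as NIfTI (``.nii``/``.nii.gz``),
TIFF, or PNG; ROI masks are 0/nonzero rasters in the same formats.
Feature tables, ROI summaries, and predictions travel as CSV; fitted
models as JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def load_raster(path: str | Path) -> np.ndarray:
    """Read a 2D raster from NIfTI, TIFF, or PNG."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.squeeze(data).astype(float)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(str(path)).astype(float)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio
        return iio.imread(str(path)).astype(float)
    raise ValueError(f"unsupported raster format: {path.name}")


def save_raster(path: str | Path, data: np.ndarray) -> None:
    """Write a 2D raster; format chosen from the extension.

    TIFF output is 32-bit float; PNG output is 8-bit (intended for
    binary masks only); NIfTI carries the array as float32 with an
    identity affine.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    data = np.asarray(data)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
        nib.save(img, str(path))
        return
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(str(path), data.astype(np.float32))
        return
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio
        iio.imwrite(str(path), (data != 0).astype(np.uint8) * 255)
        return
    raise ValueError(f"unsupported raster format: {path.name}")


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask: any nonzero pixel is inside the ROI."""
    return load_raster(path) != 0
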