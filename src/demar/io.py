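"""File export/import helpers: TIFF and NIfTI images, JSON sidecars."""
from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import tifffile

from .projector import Geometry
from .recon import ReconImage

__all__ = [
    "save_sinogram_tiff",
    "load_sinogram_tiff",
    "save_image_nifti",
    "save_image_tiff",
]


def save_sinogram_tiff(array: np.ndarray, path, geometry: Geometry,
                       **tags) -> None:
    """Write a (views, channels) sinogram as float32 TIFF + JSON sidecar."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    sidecar = {
        "n_views": geometry.n_views,
        "angular_range_deg": geometry.angular_range_deg,
        "image_size": geometry.image_size,
        "pixel_spacing_mm": geometry.pixel_spacing_mm,
        **tags,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram_tiff(path) -> tuple[np.ndarray, dict]:
    path = pathlib.Path(path)
    array = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return array, sidecar


def save_image_nifti(img: ReconImage, path) -> None:
    """Write a reconstruction as NIfTI with spacing in the affine."""
    s = img.pixel_spacing_mm
    affine = np.diag([s, s, 1.0, 1.0])
    nib.save(nib.Nifti1Image(img.values[..., None].astype(np.float32),
                             affine), str(path))
    pathlib.Path(path).with_suffix(".json").write_text(json.dumps(
        {"semantics": img.semantics, "arm": img.arm,
         "pixel_spacing_mm": s}, indent=2))


def save_image_tiff(img: ReconImage, path, hu_offset: float = 1024.0) -> None:
    """Write an HU reconstruction as offset-encoded 16-bit TIFF."""
    if img.semantics != "HU":
        raise ValueError("TIFF export expects an HU image")
    encoded = np.clip(img.values + hu_offset, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, encoded)
    pathlib.Path(path).with_suffix(".json").write_text(json.dumps(
        {"semantics": "HU", "hu_offset": hu_offset, "arm": img.arm,
         "pixel_spacing_mm": img.pixel_spacing_mm}, indent=2))
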