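"""Readers/writers for the standard containers the pipeline uses.

Images and parameter maps travel as NIfTI (dynamics on the 4th axis, complex
dtypes preserved); k-space, masks, and the time grid live together in one
HDF5 container with named datasets ``kspace``, ``mask`` and ``time_grid``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .phantom import GroundTruth
from .pk import PKMaps

__all__ = [
    "save_image_nifti",
    "load_image_nifti",
    "save_ground_truth",
    "save_pk_maps",
    "save_acquisition",
    "load_acquisition",
    "crop_rect",
]


def save_image_nifti(path: str | Path, image: np.ndarray) -> None:
    """Write an image (2-D, 3-D, or dynamic with time on the last axis)."""
    arr = np.asarray(image)
    if np.iscomplexobj(arr):
        arr = arr.astype(np.complex64)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def load_image_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj)


def save_ground_truth(outdir: str | Path, gt: GroundTruth) -> None:
    """One NIfTI per quantity: ktrans, ve, tumor mask, background."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_image_nifti(out / "ktrans.nii.gz", gt.ktrans_map)
    save_image_nifti(out / "ve.nii.gz", gt.ve_map)
    save_image_nifti(out / "tumor_mask.nii.gz", gt.tumor_mask.astype(np.uint8))
    save_image_nifti(out / "background.nii.gz", gt.background)
    np.savetxt(out / "time_grid.txt", gt.time_grid)


def save_pk_maps(outdir: str | Path, maps: PKMaps) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_image_nifti(out / "ktrans.nii.gz", maps.ktrans)
    save_image_nifti(out / "ve.nii.gz", maps.ve)
    save_image_nifti(out / "mask.nii.gz", maps.enhancing_mask.astype(np.uint8))
    save_image_nifti(out / "rss.nii.gz", maps.rss)


def save_acquisition(path: str | Path, kspace: np.ndarray,
                     mask: np.ndarray | None = None,
                     time_grid: np.ndarray | None = None) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("kspace", data=np.asarray(kspace, dtype=np.complex64))
        if mask is not None:
            f.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))
        if time_grid is not None:
            f.create_dataset("time_grid", data=np.asarray(time_grid, dtype=float))


def load_acquisition(path: str | Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with h5py.File(str(path), "r") as f:
        for key in ("kspace", "mask", "time_grid"):
            if key in f:
                out[key] = f[key][()]
    if "kspace" not in out:
        raise KeyError("container has no 'kspace' dataset")
    return out


def crop_rect(image: np.ndarray, rows: slice, cols: slice) -> np.ndarray:
    """Rectangular in-plane crop for user-supplied data (no-op for phantoms)."""
    return np.ascontiguousarray(image[rows, cols])
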