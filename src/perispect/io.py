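"""File formats: HDF5 CSI containers, NIfTI volumes, CSV tables.

The CSI container is a single HDF5 file with datasets ``suppressed``,
``unsuppressed`` (complex, rows x cols x points), ``ppm_axis`` and
``regions`` (fixed-length strings), and the acquisition parameters stored
as root attributes — a light-weight stand-in for NIfTI-MRS-style storage.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .params import AcquisitionParams
from .synthdata import CSIGrid

_ACQ_FIELDS = ("tr", "te", "bandwidth", "n_points", "field_ppm_hz",
               "grid_shape", "voxel_size")


def save_csi(path, grid: CSIGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("suppressed", data=grid.suppressed)
        f.create_dataset("unsuppressed", data=grid.unsuppressed)
        f.create_dataset("ppm_axis", data=grid.ppm_axis)
        regions = np.asarray(grid.regions, dtype=object).astype("S16")
        f.create_dataset("regions", data=regions)
        for name in _ACQ_FIELDS:
            f.attrs[name] = getattr(grid.acq, name)


def load_csi(path) -> CSIGrid:
    with h5py.File(path, "r") as f:
        kwargs = {}
        for name in _ACQ_FIELDS:
            v = f.attrs[name]
            if name in ("grid_shape", "voxel_size"):
                v = tuple(v.tolist())
            elif name == "n_points":
                v = int(v)
            else:
                v = float(v)
            kwargs[name] = v
        acq = AcquisitionParams(**kwargs)
        return CSIGrid(
            suppressed=f["suppressed"][()],
            unsuppressed=f["unsuppressed"][()],
            ppm_axis=f["ppm_axis"][()],
            acq=acq,
            regions=f["regions"][()].astype(str),
        )


def save_nifti_pair(image: nib.Nifti1Image, labels: nib.Nifti1Image,
                    image_path, labels_path) -> None:
    nib.save(image, str(image_path))
    nib.save(labels, str(labels_path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; returns data and voxel edges (mm) from the affine."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
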