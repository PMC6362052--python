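"""NIfTI-1 / TSV serialization for phantoms, field maps and 4D series."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import FieldMap, Phantom, Volume4D

__all__ = ["save_volume", "load_volume", "save_phantom", "save_fieldmap",
           "save_map"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_volume(vol: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.voxel_size))
    img.header.set_zooms(tuple(vol.voxel_size) + (vol.tr_vol_s,))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(data=data, voxel_size=tuple(float(z) for z in zooms[:3]),
                    tr_vol_s=tr, meta=dict(source=str(path)))


def save_phantom(phantom: Phantom, out_dir: str | Path, stem: str = "phantom") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.voxel_size)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff),
             str(out / f"{stem}_labels.nii.gz"))
    nib.save(nib.Nifti1Image(phantom.baseline.astype(np.float32), aff),
             str(out / f"{stem}_baseline.nii.gz"))
    phantom.parcels.to_csv(out / f"{stem}_parcels.tsv", sep="\t", index=False)


def save_fieldmap(fmap: FieldMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(fmap.delta_f.astype(np.float32),
                             _affine(fmap.voxel_size)), str(path))


def save_map(data: np.ndarray, voxel_size, path: str | Path) -> None:
    """Save a 3D (or 4D vector) map as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             _affine(voxel_size)), str(path))
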