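"""NIfTI-1 and config I/O.

Volumes round-trip voxel sizes and TR through the NIfTI header zooms;
arrays stay in voxel index space and affines are plain scaling
matrices (registration is out of scope).
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import Volume4D


def write_volume(vol: Volume4D, path: str | Path) -> Path:
    """Write a :class:`Volume4D` as NIfTI-1 with TR in the 4th zoom."""
    path = Path(path)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (vol.tr,))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, require_4d: bool = True) -> Volume4D:
    """Read a 4D NIfTI-1 volume; errors on missing files, non-4D data
    where 4D is required, and absent TR."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        if require_4d:
            raise ValueError(f"{path} is {data.ndim}D; a 4D timeseries is required")
        data = data[..., None]
    zooms = img.header.get_zooms()
    if len(zooms) < 4 or zooms[3] <= 0:
        raise ValueError(f"{path} has no repetition time in its header")
    return Volume4D(data=data.astype(np.float64), voxel_size=tuple(zooms[:3]),
                    tr=float(zooms[3]))


def write_map(data: np.ndarray, voxel_size, path: str | Path) -> Path:
    """Write a 3D map (tSNR, PSC, rCVR, pRF parameter...) as NIfTI-1."""
    path = Path(path)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(Path(path)))
    return np.asanyarray(img.dataobj).astype(np.float64)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(cfg, fh, sort_keys=False)
        else:
            json.dump(cfg, fh, indent=2, sort_keys=False)
    return path
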