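"""Core in-memory containers shared by every pipeline stage.

All arrays live in voxel index space (x, y, z, t); NIfTI affines are not
reoriented (registration is outside this package's scope).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Volume4D:
    """A 4D magnitude fMRI volume.

    Parameters
    ----------
    data
        Real-valued array of shape ``(nx, ny, nz, nt)``.
    voxel_size
        Voxel edge lengths in mm, ``(dx, dy, dz)``.
    tr
        Repetition time in seconds.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires a 4D array, got {self.data.ndim}D")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """Return a copy carrying ``data`` with the same geometry metadata."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def mean_timeseries(self, mask: np.ndarray | None = None) -> "Timeseries":
        """Spatial-mean timeseries over ``mask`` (whole volume if None)."""
        if mask is None:
            vals = self.data.reshape(-1, self.n_timepoints).mean(axis=0)
        else:
            mask = _check_mask(mask, self.spatial_shape)
            if not mask.any():
                raise ValueError("mask is empty")
            vals = self.data[mask].mean(axis=0)
        return Timeseries(values=vals, tr=self.tr)


@dataclass
class Timeseries:
    """A single BOLD timeseries sampled once per TR."""

    values: np.ndarray
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n(self) -> int:
        return self.values.size


def _check_mask(mask: np.ndarray, spatial_shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != tuple(spatial_shape):
        raise ValueError(f"mask shape {mask.shape} != volume spatial shape {spatial_shape}")
    return mask.astype(bool)


def full_mask(vol: Volume4D) -> np.ndarray:
    return np.ones(vol.spatial_shape, dtype=bool)
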