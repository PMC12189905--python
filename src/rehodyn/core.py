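"""Core containers for volumetric fMRI data.

Two thin wrappers around numpy arrays carry the geometric metadata the
pipeline needs: :class:`BoldSeries` for 4D time series and
:class:`ScalarMap` for 3D per-voxel statistics.  Both round-trip through
NIfTI-1 via nibabel; the affine maps voxel indices to world (MNI-style)
millimetre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["BoldSeries", "ScalarMap", "default_affine", "voxel_to_world"]


def default_affine(shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Diagonal affine placing the grid centre at world origin.

    Convenient for synthetic data: coordinates behave like MNI mm
    coordinates with the middle of the volume at (0, 0, 0).
    """
    shape = tuple(shape)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_size_mm)
    affine[:3, 3] = -float(voxel_size_mm) * (np.asarray(shape) - 1) / 2.0
    return affine


def voxel_to_world(affine: np.ndarray, ijk) -> np.ndarray:
    """Map voxel indices (i, j, k) to world mm coordinates via the affine."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    out = ijk @ affine[:3, :3].T + affine[:3, 3]
    return out[0] if out.shape[0] == 1 else out


@dataclass
class BoldSeries:
    """4D BOLD data: spatial grid ``(x, y, z)`` by time, plus geometry.

    Parameters
    ----------
    data:
        float array of shape ``(nx, ny, nz, T)``.
    affine:
        4x4 voxel-to-world transform.
    tr_s:
        repetition time in seconds (sampling interval of the series).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, tr_s: float | None = None) -> "BoldSeries":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(data=data, affine=np.asarray(img.affine), tr_s=tr_s)


@dataclass
class ScalarMap:
    """3D per-voxel statistic (ReHo W, Fisher z, CV, t, ...).

    Undefined voxels are NaN in ``data`` and False in ``mask``; they are
    flagged, never silently zero.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarMap data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask is None:
            self.mask = np.isfinite(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def defined_values(self) -> np.ndarray:
        """Values at voxels that are in-mask and finite."""
        ok = self.mask & np.isfinite(self.data)
        return self.data[ok]

    def with_data(self, data: np.ndarray, mask: np.ndarray | None = None) -> "ScalarMap":
        return ScalarMap(
            data=np.asarray(data, dtype=np.float64),
            affine=self.affine,
            mask=self.mask if mask is None else mask,
        )

    def to_nifti(self) -> nib.Nifti1Image:
        out = np.where(self.mask & np.isfinite(self.data), self.data, np.nan)
        return nib.Nifti1Image(out.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, mask: np.ndarray | None = None) -> "ScalarMap":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        return cls(data=data, affine=np.asarray(img.affine), mask=mask)
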