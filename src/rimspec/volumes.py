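"""Voxel-grid containers shared by every pipeline stage.

All volumes live on axis-aligned metric grids: world coordinate of voxel
``(i, j, k)`` is ``origin_mm + index * voxel_size_mm`` (no rotation).
Volumes in mm^3 are always voxel count x voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: tissue / lesion label scheme for :class:`LabelVolume`
BACKGROUND = 0
WM = 1
GM = 2
CSF = 3
LESION_LABEL_MIN = 10


@dataclass(frozen=True)
class GridSpec:
    """Shape, spacing and origin of an axis-aligned voxel grid."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel spacing must be positive")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers (open grids)."""
        return tuple(
            (self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm[a])
            for a in range(3)
        )

    def world_to_index(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm)."""
        xyz_mm = np.asarray(xyz_mm, dtype=float)
        return (xyz_mm - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)


@dataclass
class RatioMap:
    """One scalar metabolite-ratio map (or any scalar volume) with validity mask."""

    name: str
    data: np.ndarray
    grid: GridSpec
    mask: np.ndarray | None = None  # True where the value is valid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError("data shape does not match grid shape")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def mean_over(self, voxels: np.ndarray) -> float:
        """Unweighted mean over a boolean mask or index tuple, valid voxels only."""
        if voxels.dtype == bool:
            sel = voxels & self.mask
            vals = self.data[sel]
        else:  # (3, n) index array
            vals = self.data[tuple(voxels)]
            vals = vals[self.mask[tuple(voxels)]]
        return float(np.mean(vals)) if vals.size else float("nan")


@dataclass
class LabelVolume:
    """3D integer tissue/lesion labels (0 bg, 1 WM, 2 GM, 3 CSF, >=10 lesions)."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError("label shape does not match grid shape")

    @property
    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.data)
        return [int(i) for i in ids if i >= LESION_LABEL_MIN]

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.data == lesion_id

    def brain_mask(self) -> np.ndarray:
        return self.data > BACKGROUND


def save_nifti(volume: RatioMap | LabelVolume, path: str | Path) -> None:
    if isinstance(volume, LabelVolume):
        arr, grid = volume.data.astype(np.int16), volume.grid
    else:
        arr, grid = volume.data.astype(np.float32), volume.grid
    nib.save(nib.Nifti1Image(arr, grid.affine), str(path))


def load_ratio_map(path: str | Path, name: str | None = None) -> RatioMap:
    img = nib.load(str(path))
    aff = img.affine
    grid = GridSpec(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size_mm=tuple(float(aff[a, a]) for a in range(3)),
        origin_mm=tuple(float(aff[a, 3]) for a in range(3)),
    )
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    return RatioMap(name or Path(path).stem, data, grid, mask=np.isfinite(data))


def load_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    aff = img.affine
    grid = GridSpec(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size_mm=tuple(float(aff[a, a]) for a in range(3)),
        origin_mm=tuple(float(aff[a, 3]) for a in range(3)),
    )
    return LabelVolume(np.asanyarray(img.dataobj).astype(np.int16), grid)
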