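"""Voxel-grid containers shared by the phantom and segmentation stages.

Conventions: arrays are indexed ``(x, y, z)`` with the axial (slice) axis
last; ``spacing`` is the physical voxel size in mm per axis; ``origin`` is
the physical offset in mm of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: integer class codes of the five-class tissue labeling
UNLABELED, SAT, VAT, MUSCLE, ORGAN = 0, 1, 2, 3, 4
CLASS_NAMES = {UNLABELED: "unlabeled", SAT: "sat", VAT: "vat", MUSCLE: "muscle", ORGAN: "organ"}


@dataclass
class ImageVolume:
    """A 3D scalar intensity volume on an anisotropic voxel grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 in each axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid holding ``data``."""
        return ImageVolume(data, self.spacing, self.origin)

    def save(self, path: str | Path) -> None:
        save_nifti(path, self.data, self.spacing, self.origin)

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        data, spacing, origin = load_nifti(path)
        return cls(data, spacing, origin)


@dataclass
class LabelVolume:
    """Integer tissue classes co-registered to an :class:`ImageVolume` grid.

    Valid codes: 0 unlabeled, 1 SAT, 2 VAT, 3 muscle, 4 organ.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.labels.ndim}")
        bad = np.setdiff1d(np.unique(self.labels), [UNLABELED, SAT, VAT, MUSCLE, ORGAN])
        if bad.size:
            raise ValueError(f"invalid class codes present: {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def save(self, path: str | Path) -> None:
        save_nifti(path, self.labels.astype(np.int16), self.spacing, self.origin)

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        data, spacing, origin = load_nifti(path)
        return cls(np.rint(data).astype(np.int16), spacing, origin)


def same_grid(a: ImageVolume | LabelVolume, b: ImageVolume | LabelVolume) -> bool:
    return a.shape == b.shape and a.spacing == b.spacing and a.origin == b.origin


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"{what} are on different grids: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )


def mask_volume_cm3(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume in cm3: voxel count times voxel volume (mm3 -> cm3)."""
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def save_nifti(path: str | Path, data: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path: str | Path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return data, spacing, origin
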