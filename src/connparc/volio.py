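"""Volumetric containers, NIfTI IO, and mask construction.

Everything downstream works on a single common grid (the analysis assumes
inputs already registered to a template space).  Per-voxel tables use flat
indices in C order; the grid is always carried alongside so flat indices are
unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    GridMismatchError,
    LabelLookupError,
    VolumeFormatError,
)

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "make_gray_matter_mask",
    "erode_mask",
    "combine_roi_masks",
    "save_label_names",
    "load_label_names",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid with isotropic-or-not voxel sizes in millimeters."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        object.__setattr__(
            self, "origin_offset_mm", tuple(float(v) for v in self.origin_offset_mm)
        )
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ConfigurationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError(f"voxel sizes must be positive, got {self.voxel_size_mm}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_offset_mm
        return aff

    def flatten_coords(self, ijk: np.ndarray) -> np.ndarray:
        """(N, 3) voxel coordinates -> flat C-order indices."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.intp))
        return np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), self.shape)

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        """Flat C-order indices -> (N, 3) voxel coordinates."""
        return np.column_stack(np.unravel_index(np.asarray(flat, dtype=np.intp), self.shape))


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shapes differ: {a.shape} vs {b.shape}")


@dataclass
class BinaryMask:
    """A boolean value on every voxel of a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_inside(self) -> int:
        return int(self.data.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Flat C-order indices of in-mask voxels, ascending."""
        return np.flatnonzero(self.data.ravel(order="C"))

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.data & other.data)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.data | other.data)

    def minus(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.data & ~other.data)


@dataclass
class LabelVolume:
    """Integer-labeled atlas volume; 0 is background, every nonzero label is named."""

    grid: VolumeGrid
    labels: np.ndarray
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"label shape {self.labels.shape} does not match grid {self.grid.shape}"
            )
        self.names = {int(k): str(v) for k, v in dict(self.names).items()}
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ConfigurationError(f"labels {sorted(missing)} present but unnamed")

    @property
    def label_values(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise LabelLookupError(
            f"unknown ROI name {name!r}; available: {sorted(self.names.values())}"
        )

    def mask_of(self, name: str) -> BinaryMask:
        return BinaryMask(self.grid, self.labels == self.label_of(name))

    def nonzero_mask(self) -> BinaryMask:
        return BinaryMask(self.grid, self.labels != 0)

    def restrict(self, names: Sequence[str]) -> "LabelVolume":
        """A copy keeping only the named labels (others become background)."""
        keep = {self.label_of(n) for n in names}
        labels = np.where(np.isin(self.labels, list(keep)), self.labels, 0)
        return LabelVolume(self.grid, labels, {k: self.names[k] for k in keep})


# ---------------------------------------------------------------------------
# NIfTI IO


def read_volume(path) -> tuple[VolumeGrid, np.ndarray]:
    """Load a 3D or 4D NIfTI volume as (grid, float array)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"could not read {path} as a volume: {exc}") from exc
    if data.ndim not in (3, 4):
        raise VolumeFormatError(f"{path}: expected 3D or 4D data, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(data.shape[:3], tuple(float(z) for z in zooms),
                      tuple(float(v) for v in img.affine[:3, 3]))
    return grid, data


def write_volume(path, grid: VolumeGrid, values: np.ndarray) -> None:
    values = np.asarray(values)
    if values.shape[:3] != grid.shape:
        raise GridMismatchError(
            f"values shape {values.shape[:3]} does not match grid {grid.shape}"
        )
    img = nib.Nifti1Image(values, grid.affine())
    img.header.set_zooms(grid.voxel_size_mm + ((1.0,) if values.ndim == 4 else ()))
    nib.save(img, str(path))


def save_label_names(path, names: Mapping[int, str]) -> None:
    Path(path).write_text(json.dumps({str(k): v for k, v in names.items()}, indent=1))


def load_label_names(path) -> dict[int, str]:
    return {int(k): v for k, v in json.loads(Path(path).read_text()).items()}


# ---------------------------------------------------------------------------
# Mask construction


def make_gray_matter_mask(grid: VolumeGrid, prior: np.ndarray, threshold: float) -> BinaryMask:
    """Threshold a tissue-prior image into an analysis mask.

    Voxels with prior >= threshold are kept (values exactly at the threshold
    are inside, matching the zero-anything-below semantics of common
    thresholding tools).
    """
    prior = np.asarray(prior)
    if prior.ndim != 3:
        raise ConfigurationError(f"gray-matter prior must be 3D, got {prior.ndim}D")
    if prior.shape != grid.shape:
        raise GridMismatchError(f"prior shape {prior.shape} vs grid {grid.shape}")
    return BinaryMask(grid, prior >= threshold)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def erode_mask(mask: BinaryMask, iterations: int = 1, connectivity: int = 6) -> BinaryMask:
    """Morphological erosion; one iteration removes any in-mask voxel with a
    neighbor outside the mask (the volume boundary counts as outside).

    Default structuring element is the 6-neighbor (faces-only) cross.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    eroded = ndimage.binary_erosion(
        mask.data, structure=_STRUCTS[connectivity], iterations=iterations, border_value=0
    )
    return BinaryMask(mask.grid, eroded)


def combine_roi_masks(atlas: LabelVolume, names: Sequence[str]) -> BinaryMask:
    """Union of the named atlas labels, e.g. MeA+CoA+PAC into one seed mask."""
    out = np.zeros(atlas.grid.shape, dtype=bool)
    for name in names:
        out |= atlas.labels == atlas.label_of(name)
    return BinaryMask(atlas.grid, out)
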