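"""Voxelwise and ROI-seed functional connectivity.

The feature space for parcellation is the seed-voxel x target-voxel matrix
of Pearson correlations between BOLD time courses ("connectivity profile"
per seed voxel).  Group aggregation follows the variance-stabilized
convention: Fisher z transform, average across subjects, transform back.

The target space excludes the *entire* seed mask (not just the self voxel)
so every seed voxel has an identical target list: equal feature
dimensionality and no trivial self-similarity driving the clustering.
Excluding only the self voxel is available via ``exclude="self"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import GridMismatchError, ZeroVarianceError
from .preprocess import BoldSeries
from .volio import BinaryMask, VolumeGrid

__all__ = [
    "ConnectivityProfiles",
    "voxelwise_profiles",
    "fisher_transform",
    "group_average_profiles",
    "roi_seed_map",
]

R_CLIP = 0.999999  # correlations are clipped to +/- this before arctanh


@dataclass
class ConnectivityProfiles:
    """Seed x target correlation (or Fisher-z) matrix with explicit voxel lists."""

    grid: VolumeGrid
    seed_voxels: np.ndarray      # flat C-order indices, ascending
    target_voxels: np.ndarray
    values: np.ndarray           # (n_seed, n_target)
    scale: str = "r"             # "r" or "z"

    def __post_init__(self):
        self.seed_voxels = np.asarray(self.seed_voxels, dtype=np.intp)
        self.target_voxels = np.asarray(self.target_voxels, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.scale not in ("r", "z"):
            raise ValueError(f"scale must be 'r' or 'z', got {self.scale!r}")
        if self.values.shape != (len(self.seed_voxels), len(self.target_voxels)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.seed_voxels)} seeds x {len(self.target_voxels)} targets"
            )
        if len(np.intersect1d(self.seed_voxels, self.target_voxels)) > 0:
            raise ValueError("target voxel list must exclude every seed voxel")
        if self.scale == "r" and self.values.size and (
            np.nanmax(np.abs(self.values)) > 1.0 + 1e-12
        ):
            raise ValueError("r-scale values must lie in [-1, 1]")

    @property
    def n_seeds(self) -> int:
        return len(self.seed_voxels)

    def save(self, path) -> None:
        """Persist as .npz plus a JSON sidecar recording grid and scale."""
        path = Path(path)
        np.savez(
            path,
            values=self.values,
            seed_voxels=self.seed_voxels,
            target_voxels=self.target_voxels,
        )
        sidecar = {
            "scale": self.scale,
            "grid_shape": list(self.grid.shape),
            "voxel_size_mm": list(self.grid.voxel_size_mm),
            "origin_offset_mm": list(self.grid.origin_offset_mm),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "ConnectivityProfiles":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        grid = VolumeGrid(
            tuple(meta["grid_shape"]),
            tuple(meta["voxel_size_mm"]),
            tuple(meta["origin_offset_mm"]),
        )
        return cls(
            grid,
            arrays["seed_voxels"],
            arrays["target_voxels"],
            arrays["values"],
            meta["scale"],
        )


def _standardize_rows(x: np.ndarray, flat_indices: np.ndarray) -> np.ndarray:
    """Center and unit-norm each row; raise listing voxels with zero variance."""
    bad = np.flatnonzero(np.ptp(x, axis=1) == 0)
    if bad.size:
        raise ZeroVarianceError(flat_indices[bad])
    centered = x - x.mean(axis=1, keepdims=True)
    return centered / np.linalg.norm(centered, axis=1, keepdims=True)


def voxelwise_profiles(
    series: BoldSeries,
    seed_mask: BinaryMask,
    target_mask: BinaryMask,
) -> ConnectivityProfiles:
    """Pearson correlation of every seed voxel with every target voxel.

    The whole seed mask is removed from the target list, so all seed voxels
    share one target list: equal feature dimensionality, and no trivial
    self-similarity entering the parcellation features.  (Excluding only the
    self voxel would give each seed a different feature space, which the
    profile container deliberately forbids.)
    """
    for m in (seed_mask, target_mask):
        if m.grid.shape != series.grid.shape:
            raise GridMismatchError(
                f"mask grid {m.grid.shape} vs series grid {series.grid.shape}"
            )
    if seed_mask.n_inside == 0:
        raise ValueError("seed mask is empty")
    seeds = seed_mask.flat_indices
    targets = target_mask.flat_indices
    targets = np.setdiff1d(targets, seeds)
    if targets.size == 0:
        raise ValueError("target mask minus seed mask is empty")

    flat = series.matrix()
    s = _standardize_rows(flat[seeds], seeds)
    t = _standardize_rows(flat[targets], targets)
    r = np.clip(s @ t.T, -1.0, 1.0)
    return ConnectivityProfiles(series.grid, seeds, targets, r, scale="r")


def fisher_transform(values: np.ndarray, direction: str = "forward") -> np.ndarray:
    """Variance-stabilizing arctanh (forward) / tanh (inverse).

    Forward clips to +/-0.999999 first so degenerate |r| = 1 cases stay finite.
    """
    values = np.asarray(values, dtype=np.float64)
    if direction == "forward":
        return np.arctanh(np.clip(values, -R_CLIP, R_CLIP))
    if direction == "inverse":
        return np.tanh(values)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def group_average_profiles(profiles: list[ConnectivityProfiles]) -> ConnectivityProfiles:
    """Fisher-z average across subjects, returned on the r scale.

    All inputs must share identical seed and target voxel lists; the result is
    elementwise tanh(mean(arctanh(r))).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if not (
            np.array_equal(p.seed_voxels, first.seed_voxels)
            and np.array_equal(p.target_voxels, first.target_voxels)
        ):
            raise ValueError("profiles have mismatched seed/target voxel lists")
        if p.scale != "r":
            raise ValueError("group averaging expects r-scale profiles")
    stacked = np.stack([fisher_transform(p.values, "forward") for p in profiles])
    mean_z = stacked.mean(axis=0)
    return replace(first, values=np.tanh(mean_z), scale="r")


def roi_seed_map(
    series: BoldSeries,
    roi: BinaryMask,
    brain: BinaryMask,
    method: str = "mean_timecourse",
) -> np.ndarray:
    """Whole-brain Fisher-z connectivity map for an ROI seed.

    The seed signal is the ROI-mean time course (``method="mean_timecourse"``,
    the common seed-based convention) or the per-voxel map average
    (``method="mean_of_maps"``).  Output is a 3D array of arctanh(r) with NaN
    at ROI voxels and outside the brain mask.
    """
    if roi.grid.shape != series.grid.shape or brain.grid.shape != series.grid.shape:
        raise GridMismatchError("roi/brain masks must share the series grid")
    if roi.n_inside == 0:
        raise ValueError("ROI is empty")
    if not np.all(brain.data[roi.data]):
        raise ValueError("brain mask must contain the ROI")
    if method not in ("mean_timecourse", "mean_of_maps"):
        raise ValueError("method must be 'mean_timecourse' or 'mean_of_maps'")

    flat = series.matrix()
    roi_idx = roi.flat_indices
    out_idx = np.setdiff1d(brain.flat_indices, roi_idx)
    t = _standardize_rows(flat[out_idx], out_idx)

    if method == "mean_timecourse":
        seed = flat[roi_idx].mean(axis=0, keepdims=True)
        s = _standardize_rows(seed, np.asarray([-1]))
        r = (s @ t.T)[0]
        z = fisher_transform(r, "forward")
    else:
        s = _standardize_rows(flat[roi_idx], roi_idx)
        z = fisher_transform(np.clip(s @ t.T, -1, 1), "forward").mean(axis=0)

    out = np.full(series.grid.n_voxels, np.nan)
    out[out_idx] = z
    return out.reshape(series.grid.shape)
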