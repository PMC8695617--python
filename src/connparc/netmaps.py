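"""Group-level network maps: TFCE, sign-flip FWE correction, Venn partition.

The group statistic is a one-sample t on per-subject Fisher-z seed maps.
Threshold-free cluster enhancement integrates (extent)^E * (height)^H over
a ladder of thresholds, avoiding an arbitrary cluster-forming cutoff.
Family-wise error is controlled nonparametrically by the max-statistic
method under subject-level sign flips (symmetric-null assumption), and the
corrected maps are binarized at p < alpha.  Three binarized subregion maps
are then partitioned into the 8-way unique / pairwise / all-shared category
map, whose non-background sizes are the Venn voxel counts.

Inference is one-sided positive by default (the maps of interest are
regions *exhibiting* connectivity, not anticorrelations); ``two_sided=True``
enhances |t| instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError
from .volio import BinaryMask, VolumeGrid

__all__ = [
    "GroupStatMap",
    "NetworkCategory",
    "NetworkCategoryMap",
    "group_onesample_stat",
    "tfce_transform",
    "signflip_fwe",
    "assign_categories",
    "venn_counts",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

SD_FLOOR = 1e-12


@dataclass
class GroupStatMap:
    """Group statistic, TFCE enhancement and FWE-corrected p on a common mask."""

    grid: VolumeGrid
    stat: np.ndarray          # per-voxel group statistic (NaN outside mask)
    enhanced: np.ndarray      # TFCE-enhanced values (NaN outside mask)
    corrected_p: np.ndarray   # FWE-corrected p (NaN outside mask)
    mask: BinaryMask


class NetworkCategory(IntEnum):
    NONE = 0
    MEA_ONLY = 1
    COA_ONLY = 2
    PAC_ONLY = 3
    MEA_COA = 4
    MEA_PAC = 5
    COA_PAC = 6
    ALL = 7


@dataclass
class NetworkCategoryMap:
    """Mutually exclusive 8-way voxel categorization of the three networks."""

    grid: VolumeGrid
    categories: np.ndarray    # NetworkCategory codes, int array on the grid

    def __post_init__(self):
        self.categories = np.asarray(self.categories, dtype=np.int8)
        if self.categories.shape != self.grid.shape:
            raise GridMismatchError("category map shape does not match grid")


def _stack_maps(z_maps, mask: BinaryMask) -> np.ndarray:
    """(n_subjects, n_mask_voxels) matrix from per-subject 3D maps."""
    rows = []
    for m in z_maps:
        m = np.asarray(m, dtype=np.float64)
        if m.shape != mask.grid.shape:
            raise GridMismatchError(
                f"map shape {m.shape} does not match grid {mask.grid.shape}"
            )
        rows.append(m.ravel()[mask.flat_indices])
    return np.vstack(rows)


def group_onesample_stat(z_maps, mask: BinaryMask) -> np.ndarray:
    """One-sample t of subject values against 0, per in-mask voxel.

    Returns a 3D map (NaN outside the mask).  The sample sd is floored at
    1e-12 so identical-subject voxels stay finite.
    """
    data = _stack_maps(z_maps, mask)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values inside the analysis mask")
    t = _t_rows(data)
    out = np.full(mask.grid.n_voxels, np.nan)
    out[mask.flat_indices] = t
    return out.reshape(mask.grid.shape)


def _t_rows(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = np.maximum(data.std(axis=0, ddof=1), SD_FLOOR)
    return mean / (sd / np.sqrt(n))


def tfce_transform(
    stat_map: np.ndarray,
    mask: BinaryMask,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
    neighborhood: int = 6,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive-sided) statistic map.

    TFCE(v) = sum over h in {dh, 2dh, ...} up to max(map) of
    extent(h, v)^E * h^H * dh, where extent is the voxel count of the
    connected component of {map >= h} containing v.  Negative values
    contribute nothing.  When ``dh`` is None it is max(map)/n_steps.
    """
    if neighborhood not in _STRUCTS:
        raise ValueError(f"neighborhood must be one of {sorted(_STRUCTS)}")
    values = np.where(mask.data, np.asarray(stat_map, dtype=np.float64), 0.0)
    if not np.all(np.isfinite(values[mask.data])):
        raise ValueError("non-finite statistic values inside the mask")
    peak = float(values.max(initial=0.0))
    out = np.zeros(mask.grid.shape)
    if peak <= 0:
        return out
    if dh is None:
        step = peak / n_steps
    else:
        if dh <= 0:
            raise ValueError("dh must be positive")
        step = float(dh)
    struct = _STRUCTS[neighborhood]
    # integer-stepped ladder avoids float accumulation dropping the top rung
    n_rungs = int(np.floor(peak / step * (1 + 1e-9)))
    for i in range(1, n_rungs + 1):
        h = i * step
        supra = values >= h
        comp, n_comp = ndimage.label(supra, structure=struct)
        if n_comp:
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            out += np.where(supra, (sizes[comp].astype(float) ** E) * (h ** H) * step, 0.0)
    return out


def signflip_fwe(
    z_maps,
    mask: BinaryMask,
    n_perms: int = 1000,
    alpha: float = 0.05,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    neighborhood: int = 6,
    seed: int = 0,
    two_sided: bool = False,
) -> tuple[GroupStatMap, BinaryMask]:
    """Max-TFCE family-wise error correction under subject sign flips.

    Each permutation multiplies every subject's map by an independent random
    +/-1, recomputes the t map and its TFCE enhancement, and records the
    maximum enhanced value over the mask.  corrected p(v) =
    (1 + #{perm maxima >= enhanced(v)}) / (1 + n_perms); the binary map
    keeps voxels with corrected p < alpha.
    """
    if n_perms < 100:
        raise ValueError("n_perms < 100 is too coarse for FWE at alpha 0.05")
    data = _stack_maps(z_maps, mask)
    n_subj = data.shape[0]
    if n_subj < 4:
        raise ValueError("need at least 4 subjects for sign-flip inference")

    def enhanced_from(matrix: np.ndarray) -> np.ndarray:
        t = _t_rows(matrix)
        if two_sided:
            t = np.abs(t)
        vol = np.zeros(mask.grid.shape)
        vol[mask.data] = t
        return tfce_transform(vol, mask, E=E, H=H, n_steps=n_steps,
                              neighborhood=neighborhood)

    obs_t = np.full(mask.grid.n_voxels, np.nan)
    obs_t[mask.flat_indices] = _t_rows(data)
    observed = enhanced_from(data)

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    maxima = np.empty(n_perms)
    for i in range(n_perms):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        maxima[i] = enhanced_from(data * signs[:, None]).max(initial=0.0)

    obs_in = observed[mask.data]
    counts = (maxima[None, :] >= obs_in[:, None]).sum(axis=1)
    p_in = (1.0 + counts) / (1.0 + n_perms)

    corrected = np.full(mask.grid.n_voxels, np.nan)
    corrected[mask.flat_indices] = p_in
    corrected = corrected.reshape(mask.grid.shape)
    enhanced = np.where(mask.data, observed, np.nan)
    binary = BinaryMask(mask.grid, np.where(mask.data, corrected < alpha, False))
    stat_map = GroupStatMap(
        grid=mask.grid,
        stat=obs_t.reshape(mask.grid.shape),
        enhanced=enhanced,
        corrected_p=corrected,
        mask=mask,
    )
    return stat_map, binary


def assign_categories(
    binary_mea: BinaryMask, binary_coa: BinaryMask, binary_pac: BinaryMask
) -> NetworkCategoryMap:
    """8-way partition of voxels by membership in the three binarized networks."""
    grid = binary_mea.grid
    for m in (binary_coa, binary_pac):
        if m.grid.shape != grid.shape:
            raise GridMismatchError("binary maps must share one grid")
    mea, coa, pac = binary_mea.data, binary_coa.data, binary_pac.data
    codes = np.full(grid.shape, NetworkCategory.NONE, dtype=np.int8)
    codes[mea & ~coa & ~pac] = NetworkCategory.MEA_ONLY
    codes[~mea & coa & ~pac] = NetworkCategory.COA_ONLY
    codes[~mea & ~coa & pac] = NetworkCategory.PAC_ONLY
    codes[mea & coa & ~pac] = NetworkCategory.MEA_COA
    codes[mea & ~coa & pac] = NetworkCategory.MEA_PAC
    codes[~mea & coa & pac] = NetworkCategory.COA_PAC
    codes[mea & coa & pac] = NetworkCategory.ALL
    return NetworkCategoryMap(grid, codes)


def venn_counts(category_map: NetworkCategoryMap) -> dict[NetworkCategory, int]:
    """Voxel count per non-background category; sums to the 3-map union size."""
    flat = category_map.categories.ravel()
    return {
        cat: int(np.sum(flat == cat))
        for cat in NetworkCategory
        if cat != NetworkCategory.NONE
    }
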