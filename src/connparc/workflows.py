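"""Study-level workflows tying the stages together on phantom data.

These routines are what the command-line pipeline, the validation suite and
the reproduction script all call: phantom simulation -> light cleaning
(detrend + nuisance regression) -> group connectivity profiles ->
parcellation / permutation tests, plus the null-calibration loops.

Phantom-scale analyses deliberately skip band-pass filtering and spatial
smoothing: the planted latents already live in the low-frequency band, and
smoothing at these block sizes would mix voxels across planted boundaries.
Both steps remain available in :mod:`connparc.preprocess` and the CLI.
"""

from __future__ import annotations

import numpy as np

from . import parcellation as parc
from . import permstats
from .connectivity import (
    ConnectivityProfiles,
    group_average_profiles,
    voxelwise_profiles,
)
from .netmaps import signflip_fwe
from .phantom import (
    PhantomConfig,
    PhantomDataset,
    default_config,
    simulate_cohort,
    small_null_config,
)
from .preprocess import BoldSeries, clean_series
from .volio import BinaryMask

__all__ = [
    "clean_dataset",
    "subregion_masks",
    "group_profiles",
    "parcellation_recovery",
    "separation_analysis",
    "null_separation_calibration",
    "fwe_noise_calibration",
    "null_fisher_z_sample",
]


def clean_dataset(ds: PhantomDataset, detrend_order: int = 2,
                  regress: bool = True) -> list[BoldSeries]:
    """Detrend (and nuisance-regress) every subject; no drop/band-pass/smooth."""
    out = []
    for series, table in zip(ds.subjects, ds.nuisance):
        out.append(
            clean_series(
                series,
                nuisance=table if regress else None,
                drop_n=0,
                detrend_order=detrend_order,
                band=None,
                sigma_mm=0.0,
                grand_mean=None,
            )
        )
    return out


def subregion_masks(ds: PhantomDataset, olfactory_only: bool = False,
                    include_shared_target: bool = True
                    ) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """(seed mask, target mask, olfactory mask) from the phantom ground truth.

    The seed mask is the union of planted subregions (olfactory ones only if
    requested); the target mask is the union of all their target blocks
    (plus the shared block by default).
    """
    grid = ds.config.grid
    seed = np.zeros(grid.shape, dtype=bool)
    olf = np.zeros(grid.shape, dtype=bool)
    target = np.zeros(grid.shape, dtype=bool)

    from .phantom import _voxset_flat  # shared voxel-set expansion

    for s in ds.config.subregions:
        if olfactory_only and not s.olfactory:
            continue
        flat = _voxset_flat(ds.config, s.voxels)
        seed.ravel()[flat] = True
        if s.olfactory:
            olf.ravel()[flat] = True
        for t in s.targets:
            target.ravel()[_voxset_flat(ds.config, t)] = True
    if include_shared_target and ds.config.shared_targets is not None:
        target.ravel()[_voxset_flat(ds.config, ds.config.shared_targets)] = True
    return BinaryMask(grid, seed), BinaryMask(grid, target), BinaryMask(grid, olf)


def group_profiles(subjects: list[BoldSeries], seed_mask: BinaryMask,
                   target_mask: BinaryMask) -> ConnectivityProfiles:
    """Per-subject voxelwise profiles, Fisher-z averaged to one group matrix."""
    per_subject = [voxelwise_profiles(s, seed_mask, target_mask) for s in subjects]
    return group_average_profiles(per_subject)


def parcellation_recovery(
    cfg: PhantomConfig | None = None,
    k: int = 3,
    n_replicates: int = 20,
    olfactory_only: bool = True,
    run_proportion_test: bool = False,
    n_perms: int = 1000,
) -> dict:
    """Simulate, parcellate at ``k``, and score recovery against ground truth.

    Returns the adjusted Rand index between recovered clusters and the
    hemisphere-agnostic planted labels, the mean within-network voxelwise r
    of the group profiles, and (optionally) the ROI-proportion permutation
    test restricted to the seed subregions.
    """
    cfg = cfg if cfg is not None else default_config()
    ds = simulate_cohort(cfg)
    cleaned = clean_dataset(ds)
    seed_mask, target_mask, _ = subregion_masks(ds, olfactory_only=olfactory_only)
    profiles = group_profiles(cleaned, seed_mask, target_mask)
    result = parc.kmeans_parcellate(
        profiles, k=k, n_replicates=n_replicates, seed=cfg.master_seed
    )
    truth_ids = ds.truth.ids_for(result.seed_voxels)
    ari = parc.adjusted_rand_index(result.cluster_of, truth_ids)
    out = {
        "result": result,
        "truth_ids": truth_ids,
        "ari": ari,
        "mean_within_network_r": _mean_within_network_r(ds, profiles),
        "dataset": ds,
    }
    if run_proportion_test:
        roi_names = [s.name for s in ds.config.subregions
                     if s.olfactory or not olfactory_only]
        if ds.config.mirror_symmetry:
            roi_names = [n + sfx for n in roi_names for sfx in ("_lh", "_rh")]
        atlas = ds.atlas.restrict(roi_names)
        out["proportion_test"] = permstats.proportion_permutation_test(
            result, atlas, n_perms=n_perms, seed=cfg.master_seed
        )
    return out


def _mean_within_network_r(ds: PhantomDataset, profiles: ConnectivityProfiles) -> float:
    """Mean group-level r between each seed voxel and its own target block."""
    from .phantom import _voxset_flat

    total, count = 0.0, 0
    for s in ds.config.subregions:
        sub_flat = _voxset_flat(ds.config, s.voxels)
        tgt_flat = np.concatenate([_voxset_flat(ds.config, t) for t in s.targets])
        rows = np.isin(profiles.seed_voxels, sub_flat)
        cols = np.isin(profiles.target_voxels, tgt_flat)
        if rows.any() and cols.any():
            block = profiles.values[np.ix_(rows, cols)]
            total += float(block.sum())
            count += block.size
    return total / count if count else float("nan")


def matched_proportion_summary(
    result: parc.ParcellationResult,
    test: permstats.ProportionTestResult,
    atlas,
) -> dict:
    """Align clusters to ROIs and split cells into matched-diagonal vs rest.

    "Enriched" means significantly *more* voxels than the shuffle null
    (corrected p < alpha and z > 0), the sense in which matched cells are
    expected to stand out.
    """
    mapping = parc.match_clusters(result, atlas)
    col_of = {lab: j for j, lab in enumerate(test.roi_labels)}
    enriched = test.significant & (test.z_matrix > 0)
    diag_cells = [(c - 1, col_of[roi]) for c, roi in mapping.items()]
    diag_mask = np.zeros_like(enriched, dtype=bool)
    for i, j in diag_cells:
        diag_mask[i, j] = True
    return {
        "mapping": mapping,
        "diag_z": np.asarray([test.z_matrix[i, j] for i, j in diag_cells]),
        "diag_enriched": np.asarray([enriched[i, j] for i, j in diag_cells]),
        "offdiag_enriched": enriched[~diag_mask],
    }


def separation_analysis(
    ds: PhantomDataset,
    n_perms: int = 10000,
    n_replicates: int = 20,
    seed: int | None = None,
) -> permstats.PermutationResult:
    """k=2 parcellation of the full (olfactory + non-olfactory) seed set,
    followed by the olfactory-separation permutation test."""
    seed = ds.config.master_seed if seed is None else seed
    cleaned = clean_dataset(ds)
    seed_mask, target_mask, olf_mask = subregion_masks(ds, olfactory_only=False)
    profiles = group_profiles(cleaned, seed_mask, target_mask)
    result = parc.kmeans_parcellate(profiles, k=2, n_replicates=n_replicates, seed=seed)
    return permstats.olfactory_separation_test(
        result, olf_mask, n_perms=n_perms, seed=seed
    )


def null_separation_calibration(
    n_replicates: int = 200,
    n_perms: int = 500,
    master_seed: int = 0,
    kmeans_replicates: int = 8,
) -> dict:
    """Type-I-error calibration of the separation test on null phantoms.

    Each replicate simulates a fresh coupling-0 phantom, parcellates at k=2
    and runs the separation test; returns the fraction of replicates with
    |z| > 1.96 (nominal ~5%).
    """
    zs = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = small_null_config(master_seed=(master_seed * 100003 + i) & 0x7FFFFFFF)
        ds = simulate_cohort(cfg)
        res = separation_analysis(
            ds, n_perms=n_perms, n_replicates=kmeans_replicates
        )
        zs[i] = res.z
    return {
        "z_values": zs,
        "rejection_rate": float(np.mean(np.abs(zs) > 1.96)),
        "n_replicates": n_replicates,
    }


def fwe_noise_calibration(
    n_replicates: int = 200,
    n_subjects: int = 12,
    shape: tuple[int, int, int] = (6, 6, 6),
    n_perms: int = 200,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> dict:
    """Family-wise error calibration of sign-flip max-TFCE on pure-noise maps.

    Subject maps are drawn i.i.d. standard normal on every mask voxel — the
    exact null the sign-flip construction assumes — and the fraction of
    replicate cohorts with any suprathreshold voxel is returned (nominal
    ~alpha).
    """
    from .volio import VolumeGrid

    grid = VolumeGrid(shape)
    mask = BinaryMask(grid, np.ones(shape, dtype=bool))
    rng = np.random.default_rng(int(master_seed) & 0x7FFFFFFF)
    any_hit = np.zeros(n_replicates, dtype=bool)
    for i in range(n_replicates):
        maps = rng.standard_normal((n_subjects,) + shape)
        _, binary = signflip_fwe(
            list(maps), mask, n_perms=n_perms, alpha=alpha,
            seed=int(rng.integers(2**31 - 1)),
        )
        any_hit[i] = binary.n_inside > 0
    return {
        "rejection_rate": float(any_hit.mean()),
        "n_replicates": n_replicates,
    }


def null_fisher_z_sample(
    n_pairs: int = 10000,
    n_timepoints: int = 300,
    master_seed: int = 0,
) -> np.ndarray:
    """Scaled Fisher-z correlations of disjoint voxel pairs on noise phantoms.

    Simulates coupling-0, nuisance-free phantoms, pairs distinct brain voxels
    (each voxel used at most once per subject, so samples are independent)
    and returns arctanh(r) * sqrt(T - 3) — standard normal under the null.
    """
    samples: list[np.ndarray] = []
    batch = 0
    while sum(s.size for s in samples) < n_pairs:
        cfg = small_null_config(
            master_seed=(master_seed * 99991 + batch) & 0x7FFFFFFF,
            n_subjects=8,
            n_timepoints=n_timepoints,
            drift_coeffs_sd=0.0,
            n_motion_regressors=0,
            tissue_amplitude=0.0,
            baseline=0.0,
        )
        ds = simulate_cohort(cfg)
        rng = np.random.default_rng([int(master_seed) & 0x7FFFFFFF, 7, batch])
        for series in ds.subjects:
            flat = series.matrix()
            order = rng.permutation(flat.shape[0])
            half = flat.shape[0] // 2
            a = flat[order[:half]]
            b = flat[order[half:2 * half]]
            az = (a - a.mean(1, keepdims=True))
            bz = (b - b.mean(1, keepdims=True))
            r = (az * bz).sum(1) / (
                np.linalg.norm(az, axis=1) * np.linalg.norm(bz, axis=1)
            )
            samples.append(np.arctanh(r) * np.sqrt(n_timepoints - 3))
        batch += 1
    return np.concatenate(samples)[:n_pairs]
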