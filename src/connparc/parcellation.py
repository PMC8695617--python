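"""Connectivity-based parcellation via correlation-distance k-means.

Seed voxels are clustered by the similarity of their whole-brain
connectivity profiles.  The dissimilarity between a profile x and a
centroid c is 1 - Pearson(x, c) (profiles are centered before correlating,
i.e. genuine Pearson rather than cosine); centroids are arithmetic means of
member profiles.  The best of ``n_replicates`` seeded k-means++
initializations (lowest summed correlation distance) is returned, so the
result is a deterministic function of (profiles, k, n_replicates, seed).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .connectivity import ConnectivityProfiles
from .errors import ZeroVarianceError
from .volio import LabelVolume, VolumeGrid

__all__ = [
    "ParcellationResult",
    "kmeans_parcellate",
    "match_clusters",
    "adjusted_rand_index",
]


@dataclass
class ParcellationResult:
    """Cluster label (1..k) per seed voxel plus clustering diagnostics."""

    grid: VolumeGrid
    seed_voxels: np.ndarray
    cluster_of: np.ndarray       # int in 1..k, aligned with seed_voxels
    k: int
    objective: float             # sum of correlation distances to assigned centroids
    n_replicates: int
    seed: int
    degenerate: bool = False     # True if any label ended up empty
    centroids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.seed_voxels = np.asarray(self.seed_voxels, dtype=np.intp)
        self.cluster_of = np.asarray(self.cluster_of, dtype=np.int32)
        if self.cluster_of.shape != self.seed_voxels.shape:
            raise ValueError("cluster_of must align with seed_voxels")

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_of, minlength=self.k + 1)[1:]

    def to_tsv(self, path) -> None:
        ijk = np.column_stack(np.unravel_index(self.seed_voxels, self.grid.shape))
        pd.DataFrame(
            {
                "flat_index": self.seed_voxels,
                "x": ijk[:, 0],
                "y": ijk[:, 1],
                "z": ijk[:, 2],
                "cluster": self.cluster_of,
            }
        ).to_csv(Path(path), sep="\t", index=False)

    def diagnostics(self) -> dict:
        return {
            "k": int(self.k),
            "objective": float(self.objective),
            "n_replicates": int(self.n_replicates),
            "seed": int(self.seed),
            "degenerate": bool(self.degenerate),
            "cluster_sizes": [int(s) for s in self.cluster_sizes()],
        }

    def to_label_volume(self, names: dict[int, str] | None = None) -> LabelVolume:
        labels = np.zeros(self.grid.shape, dtype=np.int32)
        labels.ravel()[self.seed_voxels] = self.cluster_of
        names = names or {c: f"cluster_{c}" for c in range(1, self.k + 1)}
        return LabelVolume(self.grid, labels, names)


def _center_unit(x: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm (zero rows stay zero)."""
    c = x - x.mean(axis=1, keepdims=True)
    n = np.linalg.norm(c, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return c / n


def _corr_distance(xu: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson(x, c) given pre-standardized rows xu and raw centroids."""
    cu = _center_unit(centroids)
    return 1.0 - xu @ cu.T


def _plusplus_init(xu: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding under correlation distance."""
    n = xu.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    d = _corr_distance(xu, xu[[first]]).ravel()
    for _ in range(1, k):
        w = np.maximum(d, 0.0)
        total = w.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=w / total))
        chosen.append(idx)
        d = np.minimum(d, _corr_distance(xu, xu[[idx]]).ravel())
    return xu[chosen].copy()


def _lloyd(
    x: np.ndarray, xu: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, float, np.ndarray]:
    centroids = _plusplus_init(xu, k, rng)
    labels = np.full(x.shape[0], -1)
    for _ in range(max_iter):
        dist = _corr_distance(xu, centroids)
        new_labels = dist.argmin(axis=1)
        # repair empty clusters: reseed at the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                assigned = dist[np.arange(len(new_labels)), new_labels]
                far = int(assigned.argmax())
                centroids[c] = x[far]
                dist = _corr_distance(xu, centroids)
                new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = x[labels == c].mean(axis=0)
    dist = _corr_distance(xu, centroids)
    objective = float(dist[np.arange(len(labels)), labels].sum())
    return labels, objective, centroids


def kmeans_parcellate(
    profiles: ConnectivityProfiles,
    k: int,
    n_replicates: int = 50,
    seed: int = 0,
    max_iter: int = 300,
) -> ParcellationResult:
    """Cluster seed voxels by connectivity profile with correlation-distance k-means."""
    x = np.asarray(profiles.values, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles contain non-finite values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.n_seeds:
        raise ValueError(f"k={k} exceeds the {profiles.n_seeds} seed voxels")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ZeroVarianceError(
            profiles.seed_voxels[flat],
            f"constant connectivity profile at voxels {profiles.seed_voxels[flat][:10].tolist()}",
        )
    xu = _center_unit(x)

    best = None
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, rep]))
        labels, objective, centroids = _lloyd(x, xu, k, rng, max_iter=max_iter)
        if best is None or objective < best[1]:
            best = (labels, objective, centroids)
    labels, objective, centroids = best
    sizes = np.bincount(labels, minlength=k)
    degenerate = bool(np.any(sizes == 0))
    if degenerate:
        warnings.warn("parcellation ended with an empty cluster; flagged degenerate")
    return ParcellationResult(
        grid=profiles.grid,
        seed_voxels=profiles.seed_voxels,
        cluster_of=labels + 1,
        k=k,
        objective=objective,
        n_replicates=n_replicates,
        seed=seed,
        degenerate=degenerate,
        centroids=centroids,
    )


def overlap_matrix(result: ParcellationResult, atlas: LabelVolume) -> tuple[np.ndarray, list[int]]:
    """Voxel-count overlap of each cluster (rows) with each atlas ROI (columns)."""
    roi_labels = atlas.label_values
    atlas_flat = atlas.labels.ravel()[result.seed_voxels]
    counts = np.zeros((result.k, len(roi_labels)), dtype=np.int64)
    for ci in range(result.k):
        members = atlas_flat[result.cluster_of == ci + 1]
        for rj, lab in enumerate(roi_labels):
            counts[ci, rj] = int(np.sum(members == lab))
    return counts, roi_labels


def match_clusters(result: ParcellationResult, atlas: LabelVolume) -> dict[int, int]:
    """Optimal one-to-one cluster -> ROI-label assignment by total overlap.

    The overlap matrix is padded to square with zeros when cluster and ROI
    counts differ.  Ties are broken deterministically: among maximizing
    assignments, the lexicographically smallest (lowest cluster index gets
    the lowest ROI label) wins; for more than 7 rows the (deterministic)
    Hungarian solution is used instead.
    """
    counts, roi_labels = overlap_matrix(result, atlas)
    if counts.sum() == 0:
        warnings.warn("clusters and atlas ROIs have no overlapping voxels")
    n = max(counts.shape)
    padded = np.zeros((n, n), dtype=np.int64)
    padded[: counts.shape[0], : counts.shape[1]] = counts

    if n <= 7:
        best_perm, best_total = None, -1
        for perm in itertools.permutations(range(n)):
            total = int(padded[np.arange(n), perm].sum())
            if total > best_total:
                best_total, best_perm = total, perm
        cols = list(best_perm)
    else:
        rows, cols_arr = linear_sum_assignment(-padded)
        cols = [int(c) for _, c in sorted(zip(rows, cols_arr))]

    mapping = {}
    for ci in range(result.k):
        rj = cols[ci]
        if rj < len(roi_labels):
            mapping[ci + 1] = roi_labels[rj]
    return mapping


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand agreement between two partitions (1 = identical)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))
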