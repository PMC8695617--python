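"""Label-shuffle permutation statistics with normal-fit z scores.

Two tests are implemented on top of shared machinery:

* the k=2 olfactory-separation test — difference in the percentage of
  olfactory voxels between the two parcellation clusters, against a null in
  which the olfactory/non-olfactory voxel labels are shuffled;
* the k=3 (or general k) cluster-by-ROI proportion test — proportion of each
  cluster's voxels falling in each anatomical ROI, against a null in which
  the ROI labels are shuffled across seed voxels, with Bonferroni control
  over all k x R cells.

In both, the permuted statistics are summarized by a fitted normal
(sample mean, n-1 sd); z = (observed - mean) / sd and the p-value comes from
the normal CDF (two-sided by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateNullError, DegenerateTestError
from .parcellation import ParcellationResult
from .volio import BinaryMask, LabelVolume

__all__ = [
    "PermutationResult",
    "ProportionTestResult",
    "z_from_null",
    "p_from_z",
    "olfactory_separation_test",
    "proportion_matrix",
    "proportion_permutation_test",
]


@dataclass
class PermutationResult:
    """Observed statistic, fitted null, z, p, and the permutation bookkeeping."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perms: int
    tail: str
    rng_seed: int
    null_draws: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path, include_draws: bool = False) -> None:
        payload = {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p": self.p,
            "n_perms": self.n_perms,
            "tail": self.tail,
            "rng_seed": self.rng_seed,
        }
        if include_draws and self.null_draws is not None:
            payload["null_draws"] = [float(v) for v in self.null_draws]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class ProportionTestResult:
    """Per-cell proportions, z, p and corrected significance for k clusters x R ROIs."""

    proportions: np.ndarray
    z_matrix: np.ndarray
    p_matrix: np.ndarray
    significant: np.ndarray
    alpha: float
    correction: str
    n_perms: int
    rng_seed: int
    roi_labels: list[int]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "proportions": self.proportions.tolist(),
                    "z_matrix": self.z_matrix.tolist(),
                    "p_matrix": self.p_matrix.tolist(),
                    "significant": self.significant.tolist(),
                    "alpha": self.alpha,
                    "correction": self.correction,
                    "n_perms": self.n_perms,
                    "rng_seed": self.rng_seed,
                    "roi_labels": self.roi_labels,
                },
                indent=1,
            )
        )


def z_from_null(observed: float, null_samples) -> tuple[float, float, float]:
    """Normal fit of the permutation distribution: (z, mean, sd) with n-1 sd."""
    null = np.asarray(null_samples, dtype=np.float64)
    if null.size < 2:
        raise ValueError("need at least 2 null samples")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError("all permutation draws are identical; z undefined")
    return (float(observed) - mean) / sd, mean, sd


def p_from_z(z: float, tail: str = "two_sided") -> float:
    """Normal-model p-value for a z score."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if tail == "two_sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    if tail == "greater":
        return float(stats.norm.sf(z))
    if tail == "less":
        return float(stats.norm.cdf(z))
    raise ValueError(f"unknown tail {tail!r}")


def _olf_indicator(result: ParcellationResult, olf_mask: BinaryMask) -> np.ndarray:
    if olf_mask.grid.shape != result.grid.shape:
        raise ValueError("olfactory mask grid differs from parcellation grid")
    return olf_mask.data.ravel()[result.seed_voxels]


def olfactory_separation_test(
    result: ParcellationResult,
    olf_mask: BinaryMask,
    n_perms: int = 10000,
    seed: int = 0,
    keep_draws: bool = True,
) -> PermutationResult:
    """k=2 test that olfactory voxels concentrate in one parcellation cluster.

    The statistic is D = pct(1) - pct(2), where pct(c) is the percentage of
    cluster c's voxels that are olfactory and clusters are ordered so the
    observed olfactory-richer cluster is first.  Each permutation shuffles
    the olfactory indicator across seed voxels (cluster assignment fixed)
    and recomputes D with the same cluster order; z and a two-sided p come
    from the normal fit of the permuted D values.
    """
    if result.k != 2:
        raise ValueError(f"separation test requires k=2, got k={result.k}")
    if n_perms < 2:
        raise ValueError("n_perms must be >= 2")
    olf = _olf_indicator(result, olf_mask)
    n_olf = int(olf.sum())
    if n_olf == 0 or n_olf == olf.size:
        raise DegenerateTestError(
            "olfactory mask must be a nonempty proper subset of the seed voxels"
        )

    in_c1 = result.cluster_of == 1
    n1, n2 = int(in_c1.sum()), int((~in_c1).sum())

    def pcts(indicator):
        p1 = 100.0 * indicator[in_c1].sum(axis=-1) / n1
        p2 = 100.0 * indicator[~in_c1].sum(axis=-1) / n2
        return p1, p2

    p1, p2 = pcts(olf.astype(float))
    if p1 >= p2:
        rich_first = in_c1
    else:
        rich_first = ~in_c1
        p1, p2 = p2, p1
    observed = p1 - p2
    n_rich = int(rich_first.sum())
    n_poor = olf.size - n_rich

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    draws = np.empty(n_perms)
    for i in range(n_perms):
        perm = rng.permutation(olf)
        d1 = 100.0 * perm[rich_first].sum() / n_rich
        d2 = 100.0 * perm[~rich_first].sum() / n_poor
        draws[i] = d1 - d2

    z, mean, sd = z_from_null(observed, draws)
    return PermutationResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        z=z,
        p=p_from_z(z, "two_sided"),
        n_perms=n_perms,
        tail="two_sided",
        rng_seed=seed,
        null_draws=draws if keep_draws else None,
    )


def _atlas_labels_on_seeds(result: ParcellationResult, atlas: LabelVolume) -> np.ndarray:
    labels = atlas.labels.ravel()[result.seed_voxels]
    if np.any(labels == 0):
        raise ValueError("every seed voxel must carry an atlas label")
    return labels


def proportion_matrix(result: ParcellationResult, atlas: LabelVolume) -> np.ndarray:
    """P[c, r] = |cluster c ∩ ROI r| / |cluster c| over the seed voxels."""
    labels = _atlas_labels_on_seeds(result, atlas)
    roi_labels = atlas.label_values
    sizes = result.cluster_sizes()
    if np.any(sizes == 0):
        raise DegenerateTestError("proportion matrix undefined with an empty cluster")
    out = np.zeros((result.k, len(roi_labels)))
    for ci in range(result.k):
        members = labels[result.cluster_of == ci + 1]
        for rj, lab in enumerate(roi_labels):
            out[ci, rj] = np.sum(members == lab) / sizes[ci]
    return out


def proportion_permutation_test(
    result: ParcellationResult,
    atlas: LabelVolume,
    n_perms: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> ProportionTestResult:
    """Shuffle ROI labels across seed voxels; per-cell normal-fit z and p.

    Bonferroni correction treats all k x R cells as one family (the whole
    displayed matrix), flagging cells with corrected p < alpha.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    labels = _atlas_labels_on_seeds(result, atlas)
    roi_labels = atlas.label_values
    observed = proportion_matrix(result, atlas)
    k, R = observed.shape
    sizes = result.cluster_sizes().astype(float)

    # one-hot encodings make each permuted matrix a single matmul
    cluster_onehot = np.zeros((labels.size, k))
    cluster_onehot[np.arange(labels.size), result.cluster_of - 1] = 1.0
    roi_onehot = np.zeros((labels.size, R))
    for rj, lab in enumerate(roi_labels):
        roi_onehot[labels == lab, rj] = 1.0

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    draws = np.empty((n_perms, k, R))
    for i in range(n_perms):
        perm = rng.permutation(labels.size)
        draws[i] = (cluster_onehot.T @ roi_onehot[perm]) / sizes[:, None]

    null_mean = draws.mean(axis=0)
    null_sd = draws.std(axis=0, ddof=1)
    if np.any(null_sd == 0):
        raise DegenerateNullError("a proportion cell has zero permutation spread")
    z = (observed - null_mean) / null_sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    if correction == "bonferroni":
        corrected = np.minimum(p * (k * R), 1.0)
    else:
        corrected = p
    return ProportionTestResult(
        proportions=observed,
        z_matrix=z,
        p_matrix=p,
        significant=corrected < alpha,
        alpha=alpha,
        correction=correction,
        n_perms=n_perms,
        rng_seed=seed,
        roi_labels=[int(v) for v in roi_labels],
    )
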