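"""Template-space BOLD time-series cleaning.

Implements the post-registration preprocessing chain: initial-volume
dropping, polynomial detrending, nuisance regression, grand-mean intensity
normalization, ideal Fourier band-pass filtering, and spatial Gaussian
smoothing.  The canonical order is

    drop -> detrend -> nuisance -> normalize -> bandpass -> smooth

exposed as :func:`clean_series`; each step is also available on its own.

Notes on conventions
--------------------
* The band-pass is an ideal discrete-Fourier filter: frequency bins with
  ``low_hz <= f <= high_hz`` are retained verbatim, everything else
  (including DC when ``low_hz > 0``) is zeroed.
* Smoothing sigma is specified in millimeters and converted to voxels via
  the grid's voxel size; the kernel is truncated at 4 sigma.
* When the nuisance step follows detrending, the regressor columns are
  projected onto the same polynomial complement first, so that the two-step
  residual equals a single joint regression (Frisch–Waugh).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError, NormalizationError
from .volio import BinaryMask, VolumeGrid

__all__ = [
    "BoldSeries",
    "NuisanceTable",
    "drop_initial_volumes",
    "detrend_poly",
    "regress_nuisance",
    "grand_mean_normalize",
    "bandpass",
    "smooth_gaussian",
    "extract_mean_signal",
    "clean_series",
]


@dataclass
class BoldSeries:
    """One subject's 4D series (x, y, z, t) on a grid, with TR metadata."""

    grid: VolumeGrid
    tr_seconds: float
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BoldSeries data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.shape:
            raise GridMismatchError(
                f"series shape {self.data.shape[:3]} vs grid {self.grid.shape}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_timepoints < 1:
            raise ValueError("series has no timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=data)

    def matrix(self, mask: BinaryMask | None = None) -> np.ndarray:
        """(n_voxels, T) view of the (optionally masked) series, C voxel order."""
        flat = self.data.reshape(-1, self.n_timepoints)
        if mask is None:
            return flat
        if mask.grid.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask grid {mask.grid.shape} vs series grid {self.grid.shape}"
            )
        return flat[mask.flat_indices]


@dataclass
class NuisanceTable:
    """Named nuisance regressors (motion_1..m, wm, csf), one row per timepoint."""

    frame: pd.DataFrame

    def __post_init__(self):
        self.frame = pd.DataFrame(self.frame).astype(float)

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def drop_initial(self, n: int) -> "NuisanceTable":
        return NuisanceTable(self.frame.iloc[n:].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NuisanceTable":
        return cls(pd.read_csv(Path(path), sep="\t"))


def drop_initial_volumes(series: BoldSeries, n: int) -> BoldSeries:
    """Discard the first ``n`` volumes (non-steady-state scans)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= series.n_timepoints:
        raise ValueError(f"cannot drop {n} of {series.n_timepoints} volumes")
    return series.with_data(series.data[..., n:])


def _poly_basis(n_timepoints: int, order: int) -> np.ndarray:
    """Vandermonde basis {1, t, ..., t^order} on t scaled to [-1, 1]."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    return np.vander(t, order + 1, increasing=True)


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residual of each row of y (n_series, T) against design (T, p)."""
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ beta).T


def detrend_poly(series: BoldSeries, order: int = 2) -> BoldSeries:
    """Remove per-voxel polynomial trends up to ``order`` (default linear+quadratic)."""
    if order < 0:
        raise ValueError("order must be nonnegative")
    if series.n_timepoints <= order + 1:
        raise ValueError(
            f"need more than {order + 1} timepoints for order-{order} detrend"
        )
    basis = _poly_basis(series.n_timepoints, order)
    flat = series.matrix()
    resid = _residualize(flat, basis)
    return series.with_data(resid.reshape(series.data.shape))


def regress_nuisance(series: BoldSeries, table: NuisanceTable) -> BoldSeries:
    """Residualize every voxel against [intercept | nuisance regressors].

    A rank-deficient design (e.g. duplicated columns) is handled by the
    minimum-norm least-squares solution; the residual depends only on the
    column span, so duplicates are harmless (a warning is emitted).
    """
    if table.n_timepoints != series.n_timepoints:
        raise ValueError(
            f"nuisance table has {table.n_timepoints} rows, series has "
            f"{series.n_timepoints} timepoints"
        )
    design = np.column_stack([np.ones(series.n_timepoints), table.values()])
    if design.shape[0] <= design.shape[1]:
        raise ValueError("design matrix must have more rows than columns")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient nuisance design; using minimum-norm solution")
    flat = series.matrix()
    resid = _residualize(flat, design)
    return series.with_data(resid.reshape(series.data.shape))


def grand_mean_normalize(
    series: BoldSeries, target: float = 10000.0, mask: BinaryMask | None = None
) -> BoldSeries:
    """Scale the whole 4D series so the (in-mask) grand mean equals ``target``."""
    if target <= 0:
        raise ValueError("target must be positive")
    values = series.matrix(mask)
    mean = float(values.mean())
    sd = float(values.std())
    if abs(mean) < 1e-9 * max(sd, 1e-30):
        raise NormalizationError(
            f"grand mean {mean:g} indistinguishable from zero (sd {sd:g})"
        )
    return series.with_data(series.data * (target / mean))


def bandpass(series: BoldSeries, low_hz: float, high_hz: float) -> BoldSeries:
    """Ideal Fourier-domain band-pass: keep bins with low_hz <= f <= high_hz."""
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low < high, got [{low_hz}, {high_hz}]")
    if high_hz > nyquist * (1 + 1e-12):
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist:g}")
    T = series.n_timepoints
    freqs = np.fft.rfftfreq(T, d=series.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(series.data, axis=3)
    spectrum[..., ~keep] = 0.0
    return series.with_data(np.fft.irfft(spectrum, n=T, axis=3))


def smooth_gaussian(obj, sigma_mm: float):
    """3D Gaussian smoothing with sigma in mm (per timepoint for 4D series).

    Accepts a BoldSeries or a plain (grid, 3D array) pair via tuple.
    Kernel truncated at 4 sigma; reflective boundaries keep constant volumes
    constant.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be nonnegative")
    if isinstance(obj, BoldSeries):
        if sigma_mm == 0:
            return obj
        sig = tuple(sigma_mm / v for v in obj.grid.voxel_size_mm) + (0.0,)
        return obj.with_data(ndimage.gaussian_filter(obj.data, sigma=sig, truncate=4.0))
    grid, volume = obj
    volume = np.asarray(volume, dtype=float)
    if sigma_mm == 0:
        return grid, volume
    sig = tuple(sigma_mm / v for v in grid.voxel_size_mm)
    return grid, ndimage.gaussian_filter(volume, sigma=sig, truncate=4.0)


def extract_mean_signal(series: BoldSeries, mask: BinaryMask) -> np.ndarray:
    """Mean in-mask time course (used for white-matter / CSF nuisance signals)."""
    if mask.n_inside == 0:
        raise ValueError("mask is empty")
    return series.matrix(mask).mean(axis=0)


def clean_series(
    series: BoldSeries,
    nuisance: NuisanceTable | None = None,
    drop_n: int = 10,
    detrend_order: int | None = 2,
    band: tuple[float, float] | None = (0.008, 0.01),
    sigma_mm: float = 3.0,
    grand_mean: float | None = 10000.0,
    mask: BinaryMask | None = None,
) -> BoldSeries:
    """Full cleaning chain: drop -> detrend -> nuisance -> normalize -> bandpass -> smooth.

    Any stage can be disabled by passing ``None`` (or 0 for drop/sigma).  When
    both detrending and nuisance regression are requested, the nuisance
    columns are first residualized against the same polynomial basis so the
    sequential result equals one joint regression.

    The grand-mean scale factor is computed from the dropped-but-otherwise-raw
    data (detrending zeroes every voxel mean, which would make the grand mean
    degenerate); since detrending and regression are linear, applying the
    scale up front is identical to scaling their residuals.
    """
    out = series
    if drop_n:
        out = drop_initial_volumes(out, drop_n)
        if nuisance is not None and nuisance.n_timepoints == series.n_timepoints:
            nuisance = nuisance.drop_initial(drop_n)
    if grand_mean is not None:
        out = grand_mean_normalize(out, grand_mean, mask=mask)
    if detrend_order is not None:
        out = detrend_poly(out, detrend_order)
    if nuisance is not None:
        if detrend_order is not None:
            basis = _poly_basis(out.n_timepoints, detrend_order)
            cols = _residualize(nuisance.values().T, basis).T
            nuisance = NuisanceTable(pd.DataFrame(cols, columns=nuisance.columns))
        out = regress_nuisance(out, nuisance)
    if band is not None:
        out = bandpass(out, band[0], band[1])
    if sigma_mm:
        out = smooth_gaussian(out, sigma_mm)
    return out
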