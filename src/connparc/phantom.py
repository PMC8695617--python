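"""Synthetic multi-subject resting-state phantom with planted networks.

The phantom emulates the statistical structure the connectivity analysis
assumes: a cohort of subjects on one grid, where the voxels of each planted
"subregion" share a latent low-frequency time course with distinct distal
"target" regions, superimposed on polynomial drift, motion-like regressors,
tissue (white-matter / CSF) nuisance signals, and Gaussian noise.

Layout of the default phantom
-----------------------------
Three "olfactory" subregions (named MeA, CoA, PAC after the amygdala
subregions the analysis is designed around) each ~60 voxels with a ~64-voxel
distal target block, plus one non-olfactory region (BLA) with its own
network.  A weak *shared* latent couples the three olfactory subregions and
a common target block — the analog of the shared olfactory-amygdala network
— which is what makes olfactory voxels mutually closer than to the
non-olfactory region in the k=2 analysis.  With ``mirror_symmetry`` the
whole layout is reflected about the mid-sagittal grid plane (x -> nx-1-x)
and each mirrored region carries the same subregion identity (same latent)
tagged with the opposite hemisphere.

The generator is a pure function of its configuration: identical configs
produce bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .preprocess import BoldSeries, NuisanceTable
from .volio import BinaryMask, LabelVolume, VolumeGrid, save_label_names, write_volume

__all__ = [
    "SubregionSpec",
    "PhantomConfig",
    "GroundTruth",
    "PhantomAtlas",
    "PhantomDataset",
    "build_phantom_atlas",
    "simulate_cohort",
    "default_config",
    "small_null_config",
    "block",
]


def block(x0, x1, y0, y1, z0, z1) -> np.ndarray:
    """(N, 3) voxel coordinates of the half-open box [x0,x1) x [y0,y1) x [z0,z1)."""
    xs, ys, zs = np.meshgrid(
        np.arange(x0, x1), np.arange(y0, y1), np.arange(z0, z1), indexing="ij"
    )
    return np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]).astype(np.intp)


@dataclass
class SubregionSpec:
    """A planted subregion: its voxels, its distal target blocks, and whether
    it belongs to the olfactory group (shares the common latent)."""

    name: str
    voxels: np.ndarray                 # (N, 3)
    targets: list[np.ndarray]          # list of (M, 3)
    olfactory: bool = True

    def __post_init__(self):
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.intp))
        self.targets = [np.atleast_2d(np.asarray(t, dtype=np.intp)) for t in self.targets]


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int]
    subregions: list[SubregionSpec]
    n_subjects: int = 20
    n_timepoints: int = 300
    tr_seconds: float = 0.555
    voxel_size_mm: float = 2.0
    coupling_amplitude: float = 1.0
    shared_amplitude: float = 0.0
    shared_targets: np.ndarray | None = None
    noise_sd: float = 1.0
    drift_coeffs_sd: float = 1.0
    n_motion_regressors: int = 6
    motion_loading_sd: float = 0.3
    tissue_amplitude: float = 1.0
    wm_voxels: np.ndarray | None = None
    csf_voxels: np.ndarray | None = None
    baseline: float = 1000.0
    latent_band: tuple[float, float] = (0.01, 0.08)
    coupling_jitter_sd: float = 0.0
    mirror_symmetry: bool = False
    master_seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if self.shared_targets is not None:
            self.shared_targets = np.atleast_2d(np.asarray(self.shared_targets, dtype=np.intp))
        for attr in ("wm_voxels", "csf_voxels"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.atleast_2d(np.asarray(v, dtype=np.intp)))
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"bad grid shape {self.grid_shape}")
        if self.coupling_amplitude < 0:
            raise ConfigurationError("coupling_amplitude must be nonnegative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.drift_coeffs_sd < 0 or self.n_motion_regressors < 0:
            raise ConfigurationError("nuisance magnitudes must be nonnegative")
        n_nuisance = self.n_motion_regressors + 2  # + wm, csf
        if self.n_timepoints <= n_nuisance + 3:
            raise ConfigurationError(
                f"n_timepoints={self.n_timepoints} too small for "
                f"{n_nuisance} nuisance regressors"
            )
        named = {}
        for s in self.subregions:
            self._check_bounds(s.voxels, s.name)
            for t in s.targets:
                self._check_bounds(t, f"target of {s.name}")
            named[s.name] = set(map(tuple, s.voxels))
        names = list(named)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if named[a] & named[b]:
                    raise ConfigurationError(
                        f"subregions {a!r} and {b!r} share voxels"
                    )
        all_sub = set().union(*named.values()) if named else set()
        for s in self.subregions:
            for t in s.targets:
                if set(map(tuple, t)) & all_sub:
                    raise ConfigurationError(
                        f"a target region of {s.name!r} overlaps a subregion"
                    )
        for label, vox in (
            ("shared_targets", self.shared_targets),
            ("wm_voxels", self.wm_voxels),
            ("csf_voxels", self.csf_voxels),
        ):
            if vox is not None:
                self._check_bounds(vox, label)
                if set(map(tuple, vox)) & all_sub:
                    raise ConfigurationError(f"{label} overlaps a subregion")

    def _check_bounds(self, vox: np.ndarray, what: str) -> None:
        if vox.size == 0:
            return
        if np.any(vox < 0) or np.any(vox >= np.asarray(self.grid_shape)):
            raise ConfigurationError(f"voxel set {what!r} lies outside grid {self.grid_shape}")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.grid_shape, (self.voxel_size_mm,) * 3)

    def mirrored(self, vox: np.ndarray) -> np.ndarray:
        """Reflection about the mid-sagittal plane: x -> nx - 1 - x."""
        out = vox.copy()
        out[:, 0] = self.grid_shape[0] - 1 - out[:, 0]
        return out

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        def arr(a):
            return None if a is None else a.tolist()

        payload = {
            "grid_shape": list(self.grid_shape),
            "n_subjects": self.n_subjects,
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "voxel_size_mm": self.voxel_size_mm,
            "coupling_amplitude": self.coupling_amplitude,
            "shared_amplitude": self.shared_amplitude,
            "shared_targets": arr(self.shared_targets),
            "noise_sd": self.noise_sd,
            "drift_coeffs_sd": self.drift_coeffs_sd,
            "n_motion_regressors": self.n_motion_regressors,
            "motion_loading_sd": self.motion_loading_sd,
            "tissue_amplitude": self.tissue_amplitude,
            "wm_voxels": arr(self.wm_voxels),
            "csf_voxels": arr(self.csf_voxels),
            "baseline": self.baseline,
            "latent_band": list(self.latent_band),
            "coupling_jitter_sd": self.coupling_jitter_sd,
            "mirror_symmetry": self.mirror_symmetry,
            "master_seed": self.master_seed,
            "subregions": [
                {
                    "name": s.name,
                    "olfactory": s.olfactory,
                    "voxels": s.voxels.tolist(),
                    "targets": [t.tolist() for t in s.targets],
                }
                for s in self.subregions
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        raw = yaml.safe_load(Path(path).read_text())
        subs = [
            SubregionSpec(
                name=s["name"],
                voxels=np.asarray(s["voxels"]),
                targets=[np.asarray(t) for t in s["targets"]],
                olfactory=bool(s.get("olfactory", True)),
            )
            for s in raw.pop("subregions")
        ]
        for key in ("shared_targets", "wm_voxels", "csf_voxels"):
            if raw.get(key) is not None:
                raw[key] = np.asarray(raw[key])
        raw["grid_shape"] = tuple(raw["grid_shape"])
        raw["latent_band"] = tuple(raw["latent_band"])
        return cls(subregions=subs, **raw)


@dataclass
class GroundTruth:
    """Per-voxel planted subregion identity (hemisphere-agnostic id + tag)."""

    flat_indices: np.ndarray       # sorted flat indices of all subregion voxels
    subregion_ids: np.ndarray      # 1..S, aligned with flat_indices
    hemispheres: np.ndarray        # 'L'/'R' ('' when not mirrored)
    olfactory: np.ndarray          # bool, aligned
    id_names: dict[int, str]

    def ids_for(self, flat: np.ndarray) -> np.ndarray:
        """Subregion ids for the given flat voxel indices (0 where unplanted)."""
        lookup = dict(zip(self.flat_indices.tolist(), self.subregion_ids.tolist()))
        return np.asarray([lookup.get(int(v), 0) for v in np.asarray(flat)])

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "flat_indices": self.flat_indices.tolist(),
                    "subregion_ids": self.subregion_ids.tolist(),
                    "hemispheres": self.hemispheres.tolist(),
                    "olfactory": self.olfactory.tolist(),
                    "id_names": {str(k): v for k, v in self.id_names.items()},
                },
                indent=1,
            )
        )


@dataclass
class PhantomAtlas:
    brain_mask: BinaryMask
    gm_prior: np.ndarray
    atlas: LabelVolume
    truth: GroundTruth


@dataclass
class PhantomDataset:
    config: PhantomConfig
    brain_mask: BinaryMask
    gm_prior: np.ndarray
    atlas: LabelVolume
    truth: GroundTruth
    subjects: list[BoldSeries]
    nuisance: list[NuisanceTable]

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        grid = self.config.grid
        written = []

        def _w(name, values):
            p = outdir / name
            write_volume(p, grid, values)
            written.append(p)

        _w("brain_mask.nii", self.brain_mask.data.astype(np.uint8))
        _w("gm_prior.nii", self.gm_prior)
        _w("atlas.nii", self.atlas.labels)
        save_label_names(outdir / "atlas_names.json", self.atlas.names)
        written.append(outdir / "atlas_names.json")
        self.truth.to_json(outdir / "ground_truth.json")
        written.append(outdir / "ground_truth.json")
        for i, (series, table) in enumerate(zip(self.subjects, self.nuisance)):
            _w(f"sub-{i:02d}_bold.nii", series.data)
            table.to_tsv(outdir / f"sub-{i:02d}_nuisance.tsv")
            written.append(outdir / f"sub-{i:02d}_nuisance.tsv")
        self.config.to_yaml(outdir / "phantom_config.yaml")
        written.append(outdir / "phantom_config.yaml")
        return written


# ---------------------------------------------------------------------------
# Construction


def _voxset_flat(cfg: PhantomConfig, vox: np.ndarray) -> np.ndarray:
    flat = cfg.grid.flatten_coords(vox)
    if cfg.mirror_symmetry:
        flat = np.concatenate([flat, cfg.grid.flatten_coords(cfg.mirrored(vox))])
    return flat


def build_phantom_atlas(cfg: PhantomConfig) -> PhantomAtlas:
    """Masks, gray-matter prior, named atlas and ground-truth labels for a config.

    Deterministic; with ``mirror_symmetry`` every region also appears
    reflected about the grid midplane under the same subregion identity,
    with hemisphere-tagged atlas names (``_lh`` / ``_rh``).
    """
    grid = cfg.grid
    brain = BinaryMask(grid, np.ones(cfg.grid_shape, dtype=bool))

    labels = np.zeros(cfg.grid_shape, dtype=np.int32)
    names: dict[int, str] = {}
    truth_flat, truth_ids, truth_hemi, truth_olf = [], [], [], []

    next_label = 1
    for sid, s in enumerate(cfg.subregions, start=1):
        flat_l = grid.flatten_coords(s.voxels)
        if cfg.mirror_symmetry:
            flat_r = grid.flatten_coords(cfg.mirrored(s.voxels))
            for flat, hemi, suffix in ((flat_l, "L", "_lh"), (flat_r, "R", "_rh")):
                labels.ravel()[flat] = next_label
                names[next_label] = s.name + suffix
                next_label += 1
                truth_flat.append(flat)
                truth_ids.append(np.full(flat.size, sid))
                truth_hemi.append(np.full(flat.size, hemi))
                truth_olf.append(np.full(flat.size, s.olfactory))
        else:
            labels.ravel()[flat_l] = next_label
            names[next_label] = s.name
            next_label += 1
            truth_flat.append(flat_l)
            truth_ids.append(np.full(flat_l.size, sid))
            truth_hemi.append(np.full(flat_l.size, ""))
            truth_olf.append(np.full(flat_l.size, s.olfactory))

    flat_all = np.concatenate(truth_flat)
    order = np.argsort(flat_all)
    truth = GroundTruth(
        flat_indices=flat_all[order],
        subregion_ids=np.concatenate(truth_ids)[order],
        hemispheres=np.concatenate(truth_hemi)[order],
        olfactory=np.concatenate(truth_olf)[order],
        id_names={i: s.name for i, s in enumerate(cfg.subregions, start=1)},
    )

    gm_prior = np.full(cfg.grid_shape, 200.0)
    for vox in (cfg.wm_voxels, cfg.csf_voxels):
        if vox is not None:
            gm_prior.ravel()[_voxset_flat(cfg, vox)] = 10.0

    return PhantomAtlas(brain, gm_prior, LabelVolume(grid, labels, names), truth)


def _bandlimited_series(rng: np.random.Generator, T: int, tr: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian series with power confined to [band] Hz."""
    x = rng.standard_normal(T)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(T, d=tr)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    y = np.fft.irfft(spec, n=T)
    sd = y.std()
    if sd == 0:
        raise ConfigurationError(
            f"latent band {band} contains no FFT bins for T={T}, TR={tr}"
        )
    return (y - y.mean()) / sd


def simulate_cohort(cfg: PhantomConfig) -> PhantomDataset:
    """Generate the full multi-subject dataset for a phantom configuration.

    Per subject (seeded from ``master_seed`` and the subject index) each
    planted network — a subregion together with its target blocks, both
    hemispheres under mirroring — receives ``coupling_amplitude`` times one
    band-limited latent; the three olfactory subregions and the shared
    target block additionally receive ``shared_amplitude`` times a common
    latent.  Drift, motion-like regressors (with per-voxel random loadings),
    tissue signals on white-matter/CSF voxels, and white Gaussian noise are
    superimposed on a constant baseline.
    """
    atlas = build_phantom_atlas(cfg)
    grid = cfg.grid
    n_vox, T = grid.n_voxels, cfg.n_timepoints

    networks = []  # (amplitude_scale, member flat indices) per latent
    for s in cfg.subregions:
        members = [_voxset_flat(cfg, s.voxels)]
        members += [_voxset_flat(cfg, t) for t in s.targets]
        networks.append(np.unique(np.concatenate(members)))
    shared_members = None
    if cfg.shared_amplitude > 0:
        parts = [_voxset_flat(cfg, s.voxels) for s in cfg.subregions if s.olfactory]
        if cfg.shared_targets is not None:
            parts.append(_voxset_flat(cfg, cfg.shared_targets))
        if parts:
            shared_members = np.unique(np.concatenate(parts))

    wm_flat = _voxset_flat(cfg, cfg.wm_voxels) if cfg.wm_voxels is not None else None
    csf_flat = _voxset_flat(cfg, cfg.csf_voxels) if cfg.csf_voxels is not None else None

    t_basis = np.linspace(-1.0, 1.0, T)
    drift_basis = np.column_stack([t_basis, t_basis**2])  # constant part = baseline

    subjects, tables = [], []
    for subj in range(cfg.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.master_seed) & 0x7FFFFFFF, subj])
        )
        amp = cfg.coupling_amplitude
        if cfg.coupling_jitter_sd > 0:
            amp = max(0.0, amp * (1.0 + rng.normal(0.0, cfg.coupling_jitter_sd)))

        data = rng.normal(0.0, cfg.noise_sd, size=(n_vox, T))
        data += cfg.baseline

        for members in networks:
            latent = _bandlimited_series(rng, T, cfg.tr_seconds, cfg.latent_band)
            data[members] += amp * latent
        if shared_members is not None:
            latent = _bandlimited_series(rng, T, cfg.tr_seconds, cfg.latent_band)
            data[shared_members] += cfg.shared_amplitude * latent

        if cfg.drift_coeffs_sd > 0:
            coeffs = rng.normal(0.0, cfg.drift_coeffs_sd, size=(n_vox, 2))
            data += coeffs @ drift_basis.T

        motion = np.column_stack(
            [
                _bandlimited_series(rng, T, cfg.tr_seconds, (0.0, 0.1))
                for _ in range(cfg.n_motion_regressors)
            ]
        ) if cfg.n_motion_regressors else np.empty((T, 0))
        if cfg.n_motion_regressors:
            loadings = rng.normal(0.0, cfg.motion_loading_sd, size=(n_vox, cfg.n_motion_regressors))
            data += loadings @ motion.T

        wm_sig = _bandlimited_series(rng, T, cfg.tr_seconds, (0.0, 0.1))
        csf_sig = _bandlimited_series(rng, T, cfg.tr_seconds, (0.0, 0.1))
        if wm_flat is not None:
            data[wm_flat] += cfg.tissue_amplitude * wm_sig
        if csf_flat is not None:
            data[csf_flat] += cfg.tissue_amplitude * csf_sig

        cols = {f"motion_{j + 1}": motion[:, j] for j in range(cfg.n_motion_regressors)}
        cols["wm"] = wm_sig
        cols["csf"] = csf_sig
        tables.append(NuisanceTable(pd.DataFrame(cols)))
        subjects.append(
            BoldSeries(grid, cfg.tr_seconds, data.reshape(cfg.grid_shape + (T,)))
        )

    return PhantomDataset(
        config=cfg,
        brain_mask=atlas.brain_mask,
        gm_prior=atlas.gm_prior,
        atlas=atlas.atlas,
        truth=atlas.truth,
        subjects=subjects,
        nuisance=tables,
    )


# ---------------------------------------------------------------------------
# Stock configurations


def default_config(
    master_seed: int = 0,
    n_subjects: int = 20,
    n_timepoints: int = 300,
    coupling_amplitude: float = 1.0,
    shared_amplitude: float = 0.4,
    mirror_symmetry: bool = False,
    **overrides,
) -> PhantomConfig:
    """The standard phantom: MeA/CoA/PAC (~60 voxels each, one ~64-voxel
    target block each, ~200 target voxels total), a non-olfactory BLA region
    with its own network, a shared olfactory target block, and WM/CSF blocks.

    The default coupling amplitude is calibrated so that mean within-network
    voxelwise r is ~0.4 after detrending and nuisance regression.
    """
    nx = 28 if mirror_symmetry else 14
    subs = []
    for i, (name, olf) in enumerate(
        [("MeA", True), ("CoA", True), ("PAC", True), ("BLA", False)]
    ):
        y0 = 1 + 4 * i
        subs.append(
            SubregionSpec(
                name=name,
                voxels=block(1, 6, y0, y0 + 4, 1, 4),
                targets=[block(8, 12, y0, y0 + 4, 5, 9)],
                olfactory=olf,
            )
        )
    return PhantomConfig(
        grid_shape=(nx, 18, 12),
        subregions=subs,
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        coupling_amplitude=coupling_amplitude,
        shared_amplitude=shared_amplitude,
        shared_targets=block(8, 12, 5, 9, 9, 12),
        wm_voxels=block(1, 4, 1, 4, 9, 12),
        csf_voxels=block(1, 4, 5, 8, 9, 12),
        mirror_symmetry=mirror_symmetry,
        master_seed=master_seed,
        **overrides,
    )


def small_null_config(master_seed: int = 0, **overrides) -> PhantomConfig:
    """A reduced phantom for replicate-heavy null calibrations: same layout
    logic as :func:`default_config` at roughly 1/6 the voxel count, 3
    subjects and 120 timepoints, with coupling fixed at 0."""
    subs = []
    for i, (name, olf) in enumerate(
        [("MeA", True), ("CoA", True), ("PAC", True), ("BLA", False)]
    ):
        y0 = 1 + 2 * i
        subs.append(
            SubregionSpec(
                name=name,
                voxels=block(1, 4, y0, y0 + 2, 1, 3),
                targets=[block(5, 8, y0, y0 + 2, 3, 5)],
                olfactory=olf,
            )
        )
    defaults = dict(
        grid_shape=(10, 12, 8),
        subregions=subs,
        n_subjects=3,
        n_timepoints=120,
        coupling_amplitude=0.0,
        shared_amplitude=0.0,
        shared_targets=block(5, 8, 3, 5, 5, 7),
        wm_voxels=block(1, 3, 9, 11, 1, 3),
        csf_voxels=block(1, 3, 9, 11, 3, 5),
        master_seed=master_seed,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)
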