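"""End-to-end pipeline: phantom -> preprocessing -> connectivity ->
parcellation -> permutation tests -> network maps, driven by one config.

Every stage writes its intermediates under the output directory and the run
ends with a ``manifest.json`` recording a content hash per artifact, so
identical configurations yield identical manifests.  A failed stage leaves
partial outputs plus a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import parcellation as parc
from . import permstats
from .connectivity import roi_seed_map
from .errors import ConfigurationError
from .netmaps import assign_categories, signflip_fwe, venn_counts
from .phantom import PhantomConfig, default_config, simulate_cohort
from .volio import BinaryMask, write_volume
from .workflows import group_profiles, subregion_masks

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("connparc")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the analysis conventions
    (10 dropped volumes, quadratic detrend, 0.008-0.01 Hz band, sigma 3 mm,
    grand mean 10000, k in {2, 3}, 10000 label permutations, alpha 0.05)."""

    out_dir: str = "connparc_out"
    phantom: PhantomConfig = field(default_factory=default_config)
    drop_n: int = 0
    detrend_order: int = 2
    band: tuple[float, float] | None = None
    sigma_mm: float = 0.0
    grand_mean: float | None = None
    k_values: tuple[int, ...] = (2, 3)
    n_replicates: int = 20
    n_perms: int = 10000
    tfce_n_perms: int = 200
    alpha: float = 0.05
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_steps: int = 100
    tfce_neighborhood: int = 6
    master_seed: int = 0

    def validate(self) -> None:
        if not self.out_dir:
            raise ConfigurationError("out_dir must be set")
        if self.n_perms < 2 or self.tfce_n_perms < 100:
            raise ConfigurationError("permutation counts too small")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")
        for k in self.k_values:
            if k < 1:
                raise ConfigurationError(f"bad k {k}")
        self.phantom.validate()

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage sub-seed fanned out from the master seed."""
        digest = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF

    def to_yaml(self, path) -> None:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k != "phantom"
        }
        payload["band"] = list(self.band) if self.band else None
        payload["k_values"] = list(self.k_values)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path, phantom: PhantomConfig | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("band"):
            raw["band"] = tuple(raw["band"])
        if raw.get("k_values"):
            raw["k_values"] = tuple(raw["k_values"])
        if phantom is not None:
            raw["phantom"] = phantom
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        # -- phantom --------------------------------------------------------
        stage = "simulate"
        log.info("stage=%s", stage)
        ds = simulate_cohort(config.phantom)
        artifacts += ds.write(out / "phantom")

        # -- preprocessing --------------------------------------------------
        stage = "preprocess"
        log.info("stage=%s drop=%d detrend=%d", stage, config.drop_n, config.detrend_order)
        from .preprocess import clean_series

        cleaned = []
        for i, (series, table) in enumerate(zip(ds.subjects, ds.nuisance)):
            c = clean_series(
                series,
                nuisance=table,
                drop_n=config.drop_n,
                detrend_order=config.detrend_order,
                band=config.band,
                sigma_mm=config.sigma_mm,
                grand_mean=config.grand_mean,
            )
            cleaned.append(c)
            p = out / "clean" / f"sub-{i:02d}_clean.nii"
            p.parent.mkdir(exist_ok=True)
            write_volume(p, c.grid, c.data)
            artifacts.append(p)

        # -- connectivity + parcellation + permutation tests ---------------
        results = {}
        for k in config.k_values:
            stage = f"parcellate_k{k}"
            log.info("stage=%s", stage)
            olf_only = k != 2
            seed_mask, target_mask, olf_mask = subregion_masks(ds, olfactory_only=olf_only)
            profiles = group_profiles(cleaned, seed_mask, target_mask)
            pp = out / f"profiles_k{k}"
            profiles.save(pp)
            artifacts += [pp.with_suffix(".npz"), pp.with_suffix(".json")]
            result = parc.kmeans_parcellate(
                profiles, k=k, n_replicates=config.n_replicates,
                seed=config.stage_seed(stage),
            )
            tsv = out / f"parcellation_k{k}.tsv"
            result.to_tsv(tsv)
            (out / f"parcellation_k{k}.json").write_text(
                json.dumps(result.diagnostics(), indent=1)
            )
            write_volume(out / f"parcellation_k{k}.nii", result.grid,
                         result.to_label_volume().labels)
            artifacts += [tsv, out / f"parcellation_k{k}.json", out / f"parcellation_k{k}.nii"]
            results[k] = result

            stage = f"permtest_k{k}"
            log.info("stage=%s n_perms=%d", stage, config.n_perms)
            if k == 2:
                test = permstats.olfactory_separation_test(
                    result, olf_mask, n_perms=config.n_perms,
                    seed=config.stage_seed(stage),
                )
                p = out / "separation_test_k2.json"
                test.to_json(p)
                artifacts.append(p)
            else:
                roi_names = [s.name for s in ds.config.subregions if s.olfactory]
                if ds.config.mirror_symmetry:
                    roi_names = [n + sfx for n in roi_names for sfx in ("_lh", "_rh")]
                atlas = ds.atlas.restrict(roi_names)
                test = permstats.proportion_permutation_test(
                    result, atlas, n_perms=config.n_perms,
                    seed=config.stage_seed(stage), alpha=config.alpha,
                )
                p = out / f"proportion_test_k{k}.json"
                test.to_json(p)
                artifacts.append(p)

        # -- subregion network maps ----------------------------------------
        stage = "netmaps"
        log.info("stage=%s tfce_perms=%d", stage, config.tfce_n_perms)
        brain = ds.brain_mask
        olf_names = [s.name for s in ds.config.subregions if s.olfactory]
        binaries = {}
        for name in olf_names:
            if ds.config.mirror_symmetry:
                roi_data = np.zeros(brain.grid.shape, dtype=bool)
                for sfx in ("_lh", "_rh"):
                    roi_data |= ds.atlas.mask_of(name + sfx).data
                roi = BinaryMask(brain.grid, roi_data)
            else:
                roi = ds.atlas.mask_of(name)
            maps = [roi_seed_map(c, roi, brain) for c in cleaned]
            analysis_mask = brain.minus(roi)
            maps = [np.where(analysis_mask.data, m, 0.0) for m in maps]
            stat_map, binary = signflip_fwe(
                maps, analysis_mask, n_perms=config.tfce_n_perms,
                alpha=config.alpha, E=config.tfce_E, H=config.tfce_H,
                n_steps=config.tfce_steps, neighborhood=config.tfce_neighborhood,
                seed=config.stage_seed(f"netmaps_{name}"),
            )
            for suffix, vol in (
                ("tstat", stat_map.stat),
                ("tfce", stat_map.enhanced),
                ("fwe_p", stat_map.corrected_p),
                ("binary", binary.data.astype(np.uint8)),
            ):
                p = out / f"net_{name}_{suffix}.nii"
                write_volume(p, brain.grid, np.nan_to_num(np.asarray(vol, dtype=float)))
                artifacts.append(p)
            binaries[name] = binary

        stage = "venn"
        cat = assign_categories(binaries[olf_names[0]], binaries[olf_names[1]],
                                binaries[olf_names[2]])
        write_volume(out / "network_categories.nii", brain.grid, cat.categories)
        counts = venn_counts(cat)
        pd.DataFrame(
            {"category": [c.name for c in counts], "n_voxels": list(counts.values())}
        ).to_csv(out / "venn_counts.tsv", sep="\t", index=False)
        (out / "network_categories.json").write_text(
            json.dumps({c.name: int(c) for c in counts}, indent=1)
        )
        artifacts += [out / "network_categories.nii", out / "venn_counts.tsv",
                      out / "network_categories.json"]

    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n")
        raise

    manifest = {
        "master_seed": config.master_seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
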