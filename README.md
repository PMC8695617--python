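# connparc

Connectivity-based parcellation and network mapping of amygdala subregions
from resting-state fMRI, with a synthetic BOLD phantom for end-to-end
validation.

## The problem

Three subregions of the human amygdala — the medial amygdala (MeA), the
cortical amygdala (CoA) and the periamygdaloid complex (PAC) — receive
direct olfactory-bulb input, and the hypothesis that they form distinct
whole-brain functional networks can be tested from resting-state BOLD data
alone: if voxels cluster by their whole-brain connectivity profiles into
groups that match the anatomical boundaries, the networks are distinct.
`connparc` implements that analysis as a reusable, tested pipeline:

1. **Preprocessing** — volume dropping, polynomial detrending, nuisance
   regression (motion, white matter, CSF), grand-mean intensity
   normalization, ideal Fourier band-pass, Gaussian smoothing.
2. **Connectivity profiles** — Pearson correlation of every seed voxel
   with every target voxel; profiles are Fisher z transformed
   (`z = arctanh r`), averaged across subjects, and transformed back.
3. **Parcellation** — k-means over the group profiles with correlation
   distance `d(x, c) = 1 − corr(x, c)`; centroids are means of member
   profiles; best of `n` seeded k-means++ replicates.
4. **Permutation statistics** — label-shuffle nulls summarized by a fitted
   normal: `z = (observed − mean_perm) / sd_perm`, two-sided
   `p = 2(1 − Φ(|z|))`. Implemented for the olfactory-vs-non-olfactory
   percentage-difference test (k = 2) and the cluster-by-ROI proportion
   matrix (k = 3, Bonferroni over all cells).
5. **Network maps** — per-subregion seed maps, one-sample t across
   subjects, threshold-free cluster enhancement
   `TFCE(v) = Σ_h e(h, v)^E · h^H · dh`, sign-flip max-statistic
   family-wise error correction, binarization at corrected p < 0.05, and
   the 7-way unique / pairwise / all-shared Venn partition of the three
   binarized networks.

Because the analysis is validated on simulated data, the package also ships
a **phantom generator**: cohorts of 4D series in which each planted
"subregion" shares a band-limited latent time course with distal "target"
regions on top of drift, motion-like and tissue nuisance signals, and
Gaussian noise — with ground-truth labels, optional left/right mirror
symmetry, and a matched null (coupling 0) variant.

## Worked example

```python
from connparc import default_config, simulate_cohort, kmeans_parcellate, adjusted_rand_index
from connparc.workflows import (clean_dataset, group_profiles, subregion_masks,
                                separation_analysis)

cfg = default_config(master_seed=1)          # 20 subjects, 300 timepoints
ds = simulate_cohort(cfg)
cleaned = clean_dataset(ds)                  # detrend + nuisance regression
seed_mask, target_mask, olf_mask = subregion_masks(ds, olfactory_only=True)
profiles = group_profiles(cleaned, seed_mask, target_mask)
result = kmeans_parcellate(profiles, k=3, n_replicates=20, seed=1)
truth = ds.truth.ids_for(result.seed_voxels)
print("ARI vs planted subregions:", adjusted_rand_index(result.cluster_of, truth))
sep = separation_analysis(ds, n_perms=10000)
print(f"olfactory separation: D = {sep.observed:.1f}%, z = {sep.z:.2f}, p = {sep.p:.1e}")
```

prints

```
ARI vs planted subregions: 1.0
olfactory separation: D = 50.0%, z = 8.94, p = 3.7e-19
```

The adjusted Rand index of 1.0 means the k = 3 parcellation recovered the
three planted subregions exactly from connectivity alone. The separation
test says the olfactory voxels concentrated in one of the two k = 2
clusters far beyond what label shuffles produce (the observed 50-point
percentage difference is ~9 null standard deviations out).

The same stages are available from the shell:

```bash
connparc run --out results/ --seed 7         # full pipeline on the default phantom
connparc simulate --out phantom/ --seed 7    # just the synthetic dataset
connparc preprocess --in phantom/sub-00_bold.nii \
    --nuisance phantom/sub-00_nuisance.tsv --drop 10 --no-band --out clean.nii
```

`connparc run` writes every intermediate (cleaned series, profiles,
parcellations, permutation JSONs, TFCE maps, Venn counts) plus a
`manifest.json` of content hashes; identical configurations reproduce
identical hashes.

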