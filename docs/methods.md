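# Methods

This note documents what `connparc` computes, the assumptions behind each
stage, the defaults and why they were chosen, and what validation on the
synthetic phantom does and does not establish about real data.

## Preprocessing model

A subject's data is a 4D series on a common template grid (registration and
motion correction are assumed done upstream; this package starts where
template-space cleaning begins). The canonical chain is

    drop -> detrend -> nuisance regression -> grand-mean normalize
         -> band-pass -> spatial smooth

with defaults: 10 initial volumes dropped, quadratic detrend, nuisance
table of six motion parameters plus mean white-matter and CSF signals
(tissue masks eroded one voxel first, so partial-volume gray matter does
not leak into the regressors), grand mean scaled to 10000, band-pass
0.008–0.01 Hz, Gaussian sigma 3 mm.

Numerical choices:

* Detrending and nuisance regression are ordinary least squares per voxel;
  when chained, the nuisance columns are first projected onto the
  polynomial complement so the sequential residual equals one joint
  regression (Frisch–Waugh). Rank-deficient designs fall back to the
  minimum-norm solution with a warning — the residual depends only on the
  column span, so duplicated regressors are harmless.
* The grand-mean scale factor is computed from the post-drop, pre-detrend
  data. Detrending zeroes every voxel mean, so a literal
  normalize-after-regression would always be degenerate; because the
  detrend/regression steps are linear, scaling first is algebraically
  identical to scaling their residuals.
* The band-pass is an ideal discrete-Fourier filter (bins with
  `low <= f <= high` kept verbatim, DC removed whenever `low > 0`). This
  is exactly testable: the output spectrum is identically zero outside the
  band and the filter is idempotent.
* The default band of 0.008–0.01 Hz is carried as configuration. At
  typical run lengths (~165 s of data at TR 0.555 s) it spans roughly one
  FFT bin, so phantom-scale analyses in this package run without the
  band-pass (and without smoothing, which at phantom block sizes would mix
  voxels across planted boundaries); both stages remain available and are
  exercised by their own unit tests.
* Smoothing sigma is interpreted in millimeters and converted through the
  grid's voxel size; the kernel is truncated at 4 sigma with reflective
  boundaries, so constant volumes are preserved.

## Connectivity and group aggregation

The parcellation feature space is the seed-voxel × target-voxel Pearson
correlation matrix. The entire seed mask is excluded from the target list
(not just each voxel's self-correlation) so that every seed voxel has the
same feature dimensionality and no trivial self-similarity drives the
clustering. Correlations are clipped to ±0.999999 before `arctanh` so
degenerate identical-series cases stay finite. Group profiles are
`tanh(mean(arctanh r))` across subjects — the variance-stabilized average —
and subject alignment is by construction, since voxel lists are stored
explicitly and checked.

ROI seed maps use the ROI-mean time course (the common seed-based
convention); a mean-of-per-voxel-maps variant is selectable. ROI voxels are
NaN in the output map, never numeric.

## Correlation-distance k-means

Distance is `1 − Pearson(x, c)` with profiles centered before correlating
(genuine Pearson, not cosine). Centroids are arithmetic means of member
profiles. Each of `n_replicates` (default 50) restarts draws a k-means++
style initialization from a replicate-specific sub-seed; Lloyd iterations
run to label convergence; an emptied cluster is repaired by reseeding its
centroid at the point farthest from its assigned centroid, keeping k fixed.
The lowest-objective replicate is returned, making the result a pure
function of (profiles, k, n_replicates, seed). k is a design input (2 for
the olfactory / non-olfactory split, 3 for the subregion parcellation);
there is no automatic model selection.

Cluster→ROI correspondence is the overlap-maximizing one-to-one assignment
(exhaustive search with a lexicographic tie-break for k ≤ 7, Hungarian
algorithm above that). Agreement is scored with the adjusted Rand index.

## Permutation statistics

Both tests summarize a shuffle null by a fitted normal: null mean and
(n−1)-denominator standard deviation of the permuted statistics, then
`z = (observed − mean)/sd` and a two-sided normal p. The two-sided
convention is fixed by the requirement that z = 4.79 maps to p = 1.7e-6.

* **Separation test (k = 2).** Statistic: difference in the percentage of
  olfactory voxels between the two clusters, with clusters ordered so the
  observed olfactory-richer one is first. Permutations shuffle the
  olfactory indicator across seed voxels with cluster assignments fixed
  (label counts preserved). Ordering by observed richness makes the
  statistic well-defined; because it effectively tests |D|, the two-sided
  normal p stays calibrated (verified: 4–6% rejection at |z| > 1.96 over
  null replicates).
* **Proportion test (general k).** `P[c, r]` = fraction of cluster c's
  voxels inside ROI r. Permutations shuffle ROI labels across seed voxels;
  each cell gets its own normal-fit z and two-sided p; Bonferroni treats
  all k·R cells as one family. With strong planted structure the
  off-diagonal cells are significantly *depleted* two-sided, so the
  workflow layer reports "enrichment" (significant and z > 0) for the
  matched-cell checks; the result object itself keeps the plain
  corrected-p contract.

Stored permutation draws allow exact re-derivation of z; all draws are
reproducible from (seed, n_perms).

## Group maps, TFCE and FWE

The group statistic is a one-sample t of subject Fisher-z maps against
zero (sd floored at 1e-12). TFCE integrates
`extent(h, v)^E · h^H · dh` over a threshold ladder `h = dh, 2dh, … ≤ max`;
defaults E = 0.5, H = 2, 100 steps (`dh = max/100`), 6-connectivity — the
canonical volumetric defaults, all configurable. Inference is one-sided
positive (the maps of interest are regions exhibiting connectivity, not
anticorrelations); a two-sided flag enhances |t|. The threshold ladder is
integer-stepped so the top rung is never lost to floating-point
accumulation.

Family-wise error: each permutation flips every subject's map by an
independent ±1 (symmetric-null assumption), the maximum enhanced value
over the mask is recorded, and `p(v) = (1 + #{maxima ≥ TFCE(v)})/(1 + n)` —
an estimator that is never zero and valid at finite n. Binarization keeps
`p < alpha`. The three binarized subregion maps are partitioned into the
eight mutually exclusive membership categories (none / three unique /
three pairwise / all-shared); the non-background category sizes are the
Venn voxel counts and sum to the union size by construction.

## The phantom

What it emulates: a cohort of subjects on one grid in which each planted
subregion and its distal target blocks share a band-limited Gaussian
latent (default passband 0.01–0.08 Hz, the low-frequency range where
resting BOLD coherence lives), superimposed on per-voxel quadratic drift
(coefficient sd 1), six motion-like low-frequency regressors with
per-voxel Gaussian loadings (sd 0.3), shared tissue signals on designated
white-matter/CSF blocks, a constant baseline of 1000, and unit-variance
white noise. Subject-level variability enters only through fresh noise and
nuisance draws by default (a coupling-jitter option exists), which keeps
group-level expectations closed-form. Simulation is a pure function of the
configuration: identical configs give bit-identical datasets, with
per-subject seeds spawned from the master seed.

The default layout has three olfactory subregions (MeA, CoA, PAC; 60
voxels each, one 64-voxel target block each) plus a non-olfactory region
(BLA) with its own network, and a weak shared latent (amplitude 0.4)
linking the three olfactory subregions to a common 48-voxel target block.
The shared component is what gives the k = 2 analysis its premise — that
olfactory subregions are mutually closer than to the non-olfactory
amygdala — and mirrors the empirically observed shared olfactory-amygdala
network. Default cohort: 20 subjects × 300 timepoints at TR 0.555 s.
The coupling amplitude default of 1.0 was calibrated once so that the mean
within-network voxelwise correlation after detrending and nuisance
regression is ≈ 0.4, a realistic resting-state effect size.

Mirror symmetry reflects every region about the mid-sagittal grid plane
(x → nx−1−x); mirrored regions carry the same subregion identity (same
latent) tagged with the opposite hemisphere, which is the simplest
testable version of bilaterally symmetric networks. The gray-matter prior
is 200 on gray voxels and 10 on tissue blocks, so the conventional
threshold of 100 reproduces the intended analysis mask.

What the phantom does *not* model: hemodynamic response shapes, actual
head displacement (only regressor-level motion proxies), scanner
artifacts, spatial autocorrelation of noise, anatomical geometry, or
between-subject anatomical variability. Passing recovery tests therefore
demonstrates the correctness and calibration of the *analysis machinery*
under the model's assumptions — not that real amygdala subregions would
parcellate this cleanly.

## Problem sizes used in validation

Chosen to make the full validation cheap enough to run routinely on one
CPU while keeping every statistical check meaningful:

* Recovery: the default 20-subject phantom, 20 independent master seeds;
  success means ARI ≥ 0.9 and all matched cluster-ROI cells enriched
  (Bonferroni α 0.05, 1000 permutations).
* Separation-test calibration: 200 replicate null phantoms at a reduced
  size (3 subjects, 10×12×8 grid, 120 timepoints, 500 permutations each).
* FWE calibration: 200 replicate cohorts of 12 subjects; maps are drawn
  i.i.d. standard normal on a 6×6×6 mask — exactly the null the sign-flip
  construction assumes — with 200 sign-flip permutations each.
* Null connectivity distribution: 12,000 disjoint voxel pairs (each voxel
  used at most once per subject, so pairs are independent) from
  nuisance-free coupling-0 phantoms at T = 300; `arctanh(r)·√(T−3)` is
  compared to N(0, 1) by Kolmogorov–Smirnov test.

## Known limitations

* The proportion test's two-sided p marks depletion as well as enrichment;
  consumers interested in the "contains significantly more voxels" reading
  should use the workflow-level enrichment summary.
* The ideal Fourier band-pass assumes stationarity and wraps circularly;
  no tapering is applied.
* The sign-flip FWE construction assumes subject maps are symmetrically
  distributed around zero under the null; heavy skew would misbehave.
* TFCE values depend mildly on the step count near the support floor;
  voxels well above threshold converge at the documented < 2% per halving
  of dh.
* k-means with correlation distance is not guaranteed to find the global
  optimum; the replicate scheme makes failures rare at these sizes but not
  impossible.
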