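# Methods

This note documents the models, conventions and numerical choices behind
`mvlight`, in the order a typical analysis uses them: the dataset
container, classifiers and partitions, measures, neighborhoods and the
searchlight, cluster-level inference, and the synthetic data used by the
tests and examples.

## The dataset container

All data — fMRI volumes, M/EEG channel/time matrices, searchlight output
maps, dissimilarity structures — live in one container: a numeric
`samples` matrix (`n_samples x n_features`), a per-sample attribute table
`sa`, a per-feature table `fa`, and general attributes `a`.  Two `sa`
columns have reserved meaning: `targets` (integer condition label) and
`chunks` (integer independence group, e.g. acquisition run).  Chunks are
the unit every cross-validation scheme respects: whole chunks stay on one
side of a fold.

Multi-dimensional feature spaces (e.g. voxel `i, j, k`, or `chan x time`)
are described by `a.fdim`, an ordered list of dimension labels with their
coordinate values; for each label there is an `fa` column of **1-based**
positions into the value list.  The same machinery exists on the sample
axis (`a.sdim`), used for dissimilarity matrices and generalization
results.  Two conventions are fixed and load-bearing:

- Dimension index columns are 1-based everywhere.  Python-level indices
  (slice selectors, neighbor lists) are 0-based.  `validate_dataset`
  flags index columns outside `[1, len(values)]`.
- When a dense dataset is flattened, the **first** dimension label varies
  fastest (Fortran-order enumeration of the grid).  `flatten`/`unflatten`
  and the NIfTI reader/writer all share this order, which is what makes
  the round trips exact.

Volumetric geometry is a 4x4 affine `a.vol.mat` mapping 1-based voxel
indices to world mm.  NIfTI stores a 0-based affine; reading applies a
unit index shift and writing reverses it symmetrically, so a write/read
round trip reproduces both the affine (to 1e-6) and the data bit-exactly
on mapped voxels.  The file's orientation is taken verbatim; no
reorientation is attempted.

`normalize` de-means or z-scores along an axis and returns the estimated
parameters so the identical transform can be applied to held-out data
(the train/test pattern).  z-scoring uses the sample standard deviation
(ddof=1); zero-variance entries become NaN with a warning rather than an
error so downstream masking can remove them.  NaNs in input data are
propagated, never dropped silently.

`chunkize` re-groups chunks into `n` balanced bins by sorting the unique
chunk values and dealing them round-robin — deterministic, and balanced to
within one chunk.  `randomize_targets` permutes targets **within** each
chunk, preserving the exchangeability structure that sign-flip and
permutation tests rely on; it is a pure function of `(dataset, seed)`.

## Classifiers and partitions

Classifiers are plain functions
`clf(samples_train, targets_train, samples_test, **opt) -> predictions`;
test targets are never passed in.

**Regularized LDA.**  Per-class means `mu_c` and the pooled within-class
covariance `S = (1/(n-C)) sum_c sum_{i in c} (x_i-mu_c)(x_i-mu_c)^T`,
regularized as `S_r = S + lambda (tr S / p) I` with `lambda = 0.01`.
Scaling by the mean diagonal keeps the regularization unit-free and the
system well-posed in the `p >> n` searchlight regime.  Prediction is
`argmax_c  mu_c^T S_r^{-1} x - (1/2) mu_c^T S_r^{-1} mu_c` with equal
class priors (balanced designs are the norm for decoding studies); ties go
to the smallest class label.

**Gaussian naive Bayes.**  Independent per-feature Gaussians per class,
variances floored at 1e-12 (constant features stay finite), empirical
class priors, ties to the smallest label.

Both are checked against independent brute-force implementations
(explicit matrix inverse and per-sample score loops; scipy densities for
naive Bayes) on batteries of random problems.

**Partition schemes** operate on chunks: `nfold` (leave-one-chunk-out),
`oddeven` (two folds by odd/even *rank* of the sorted unique chunk values,
robust to arbitrary chunk numbering), `take_k_out` (one fold per
k-combination of chunks) and `cross_grouped` (cross-decoding: for each
ordered pair of group values and each chunk, train on one group excluding
the chunk, test on the other group restricted to it).  `check_partitions`
flags train/test overlap, chunks on both sides of a fold, and classes
missing from a training set; the cross-validation measure refuses to run
on violating partitions.

## Measures

A measure maps a dataset to a dataset whose `samples` is a single column;
`sa`/`a.sdim` describe the rows.  This uniform contract is what the
searchlight engine relies on.

- `crossvalidation_measure`: per fold, train/predict; accuracy is pooled
  (total correct / total predictions) rather than averaged per fold, which
  is robust to unequal fold sizes.  Optional normalization estimates
  parameters on the training set only.  `output='predictions'` returns one
  row per sample (last fold's prediction when a sample is tested more than
  once; standard schemes test each sample exactly once).
- `correlation_measure`: split-half Fisher-z contrast.  Halves come from
  the two chunk values (or `chunkize` into two); per half and target a
  mean pattern is computed, `Z = atanh(corr(half1, half2))`, and the
  result is `sum(W * Z)` averaged over both half orderings with the
  default contrast W = diagonal `1/C` vs off-diagonal `-1/(C(C-1))`.
  Correlations are clipped to `+/-(1 - 1e-15)` (with a warning) before
  `atanh`, since noiseless toy data otherwise produces infinities.
- `target_dsm_corr_measure`: neural dissimilarity = pairwise correlation
  distance (`1 - r`) between condition patterns; the statistic is the
  Pearson (or Spearman) correlation between the upper-triangle vectors of
  the neural and target matrices.
- `dissimilarity_matrix_measure`: the raw condition-pair distances in pair
  order (1,2), (1,3), ..., (2,3), ...; `a.sdim` encodes the pair grid so
  unflattening along samples yields the square matrix.
- `dim_generalization_measure`: the train-time x test-time matrix.  The
  moved dimension lives on the sample axis (`dim_transpose`), chunks 1/2
  mark train/test.  For each position pair, window offsets within
  `radius` become extra features; offsets are restricted to those in range
  for *both* centers, so train and test feature spaces always match at the
  boundaries (the alternative — truncating each side independently —
  produces incompatible dimensionalities at the edges).  Output rows
  enumerate pairs with the train position varying fastest, matching the
  flatten convention.

## Neighborhoods and the searchlight

A neighborhood maps each center of an *output* feature space to a list of
input-feature indices: spherical (voxels within a world-mm radius, or the
`count` nearest with ties broken by `(distance, feature index)` — the
fixed-count variant equalizes pattern size across brain locations),
interval (all features within `radius` bins of a center position, across
every other dimension), channel (sensor locations within a layout-distance
radius or count; `combined_from_planar` centers on combined gradiometers
while selecting both planar channels of each location, so maps have one
value per sensor site but patterns use the raw planar data), and crossed
(Cartesian product of centers, first part varying fastest, neighbor sets
intersected).  All distances are closed-ball (`<=`).  Crossed centers with
empty intersections are kept; the searchlight emits an all-NaN column and
a warning for them.

The searchlight slices the dataset to each center's neighbors, applies the
measure, and stacks the single-column results in center order.  Centers
are independent; with `n_workers > 1` they are evaluated via joblib but
always assembled in center order, so results are identical for any worker
count.  Feature attributes of the output come from the neighborhood,
sample attributes from the measure result; all centers must produce the
same row structure.

## Cluster-level inference

`feature_adjacency` derives adjacency from the dataset dimensions: one
index step per dimension (voxels: 26-connectivity; time/frequency: +/-1
bin; channels: layout locations within a radius defaulting to 1.5x the
smallest nonzero inter-location distance, which on a square grid includes
diagonals), combined by conjunction across dimensions.  The implementation
materializes a dense boolean feature-by-feature matrix — fine for the map
sizes this package targets (10^3-10^4 features).

**TFCE.**  `TFCE(f) = sum_{h=dh, 2dh, ... <= max} e(f,h)^E h^H dh` with
`e(f,h)` the size of the `map >= h` connected component containing `f`;
defaults `E = 0.5, H = 2, dh = 0.1` (the standard parameter set).
Negative values are enhanced on the negated map and re-negated.  The
kernel processes thresholds in descending order with an incremental
union-find (numba-jitted when numba is importable; a pure-Python fallback
implements the identical algorithm), and is verified against an
independent per-threshold scipy connected-components loop.  For a
constant-height cluster (value v, size n, H=2) the dh-Riemann sum
converges to `n^E v^3 / 3` from above with error at most `n^E v^2 dh`.

**Monte-Carlo FWE.**  The observed statistic is the feature-wise
one-sample t against `h0_mean`, passed through TFCE (or fixed-threshold
cluster mass).  Null iterations multiply each participant's centered map
by an independent +/-1 (sign flip), or draw one map per participant from
user-supplied null maps with replacement; the per-iteration maximum
statistic across features forms the null distribution, and
`p(f) = (1 + #{max_null >= s(f)}) / (niter + 1)`.  This max-statistic
construction controls family-wise error by design and is simpler than
hybrid cluster-FDR schemes; feature-wise (uncorrected) permutation p
values are also exposed.  z maps are the inverse-normal transform of
`1 - p` (one-tailed) or `1 - p/2` signed by the effect (two-tailed), with
p clamped to `[1/(niter+1), 1 - 1/(niter+1)]` so z is finite on both
sides; features with zero observed statistic get z = 0.  Degenerate
zero-variance features receive t = 0 when the mean equals `h0_mean` and a
capped t (+/-50) otherwise.  Everything is a pure function of `seed`.

## Synthetic data

The generators reproduce the *structure* of real recordings — layouts,
dimensions, chunk/target bookkeeping, nominal effect sizes — with i.i.d.
Gaussian noise.  They do not emulate hemodynamic or evoked-response
dynamics, spatial noise correlations, or between-participant variance
components; passing tests therefore demonstrate correctness of the
machinery and calibration under exchangeable noise, not performance on
real data.

- `make_toy_meeg`: 18 planar channels (9 locations on a 3x3 grid, layout
  `toy9`) x 5 time bins (0-0.4 s), 3 conditions x 4 chunks by default, one
  sample per condition/chunk (`n_repeats` raises this).  Class-specific
  mean patterns (SD = `effect_size`, default 1) on a configurable
  channel/time subset plus unit noise.
- `make_toy_fmri`: a 10x10x10 volume (3 mm isotropic, diagonal affine)
  with a focal activation: class-mean patterns inside a centered 5x5x5
  region, scaled by a Gaussian falloff (sigma 1.5 voxels) around the
  region centroid, with `n_repeats = 6` samples per condition and run
  (48 samples at the 2-condition, 4-chunk default).  The taper gives the
  activation a well-defined peak; a flat-top block saturates decoding
  accuracy over a plateau of searchlight centers, which makes the location
  of the map maximum essentially arbitrary.  Real activations are peaked,
  so the taper is also the more faithful emulation.
- `make_group_maps`: per-participant maps `true_effect + N(0, noise_sd)`
  over a 1-D feature axis, one row per participant.

All generators are pure functions of their options including `seed`, and
their outputs pass `validate_dataset`.

## Calibration and recovery problem sizes

The statistical checks shipped with the package use: 100 independent
null datasets (effect 0, 5 repeats, 60 predictions each) for
chance-level decoding — fresh datasets per seed, because repeatedly
permuting one fixed dataset shares its noise across seeds and the
binomial interval then under-covers; 200 null simulations of 12
participants x 100 features with 200 sign-flip iterations for FWE
calibration at alpha = 0.05; 20 volumes for searchlight peak recovery
(33-voxel lights); and 50 simulations of a 10-feature, +1 SD group effect
in 20 participants for cluster recovery.

## Known limitations

- Surface-based (geodesic) neighborhoods and native scanner/package
  formats beyond NIfTI are out of scope; the `.plds` HDF5 container is the
  interchange format for everything non-volumetric.
- `feature_adjacency` is dense (O(n_features^2) memory); whole-brain maps
  at full resolution would need a sparse construction.
- Group inference covers the one-sample design (t against a null mean);
  factorial designs are not implemented.
- String targets are not supported in `sa.targets`; map condition names to
  integers at the I/O boundary.
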