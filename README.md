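# mvlight

Searchlight multivariate pattern analysis (MVPA) for fMRI and M/EEG data:
one dataset container for volumetric and channel/time recordings,
composable analysis measures, generalized neighborhoods, a searchlight
engine, and TFCE-based Monte-Carlo correction for multiple comparisons.

## Who this is for

Cognitive neuroscientists who want to ask *where* (and *when*) patterns of
brain activity carry information about experimental conditions: decoding
with cross-validated classifiers, split-half pattern reliability,
representational similarity analysis (RSA), and time-generalization —
each runnable over a region of interest or slid across the whole feature
space as a searchlight, with group-level inference that controls
family-wise error.

## The core ideas

**One container.**  A dataset is a samples-by-features matrix `X` plus
per-sample attributes (`targets` = condition labels, `chunks` =
independent acquisition groups), per-feature attributes, and dimension
descriptors that remember how features (voxels `i,j,k`, `chan x time`
bins, ...) fold back into arrays or NIfTI volumes.

**Measures.**  Every analysis is a function `measure(ds, **opt)` returning
a single-column dataset: cross-validated accuracy
(`#correct / #predictions` pooled over leave-one-chunk-out folds),
a split-half correlation contrast `sum W * atanh(C)` between per-condition
mean patterns, the correlation between the neural dissimilarity matrix
(1 − Pearson r between condition patterns) and a target DSM, or a full
train-time × test-time generalization matrix.

**Neighborhoods + searchlight.**  A neighborhood assigns each center a set
of input features (spherical in mm, the `count` nearest voxels, temporal
intervals, sensor-layout disks, or Cartesian products of these).  The
searchlight applies any measure at every center and stacks the results
into an information map over the centers' feature space.

**Cluster statistics.**  Maps from a group of participants are tested with
a feature-wise one-sample t transformed by threshold-free cluster
enhancement, `TFCE(f) = Σ_h e(f,h)^E h^H dh`, and calibrated by the
permutation distribution of the maximum statistic under sign flipping —
corrected p-values and signed z maps over the original feature space.

Classifiers: regularized linear discriminant analysis
(`Σ_r = Σ + 0.01·(trΣ/p)·I`, equal priors) and Gaussian naive Bayes, both
behind one uniform signature so measures can swap them freely.

## Worked example

A channel-by-time searchlight on a toy MEG dataset — 9 planar-gradiometer
pairs on a 3×3 grid, 5 time points, 3 conditions × 4 chunks
(`examples/04_meeg_channel_time_searchlight.py`):

```python
import mvlight as mv

ds = mv.make_toy_meeg(effect_size=1.5, seed=1)
layout = mv.load_layout("toy9")
nb = mv.cross_neighborhood(ds, [
    mv.channel_neighborhood(ds, layout, count=4,
                            chantype="combined_from_planar"),
    mv.interval_neighborhood(ds, "time", radius=1),
])
acc = mv.searchlight(ds, nb, mv.crossvalidation_measure,
                     opt={"partitions": mv.make_partitions(ds, "nfold")})
```

This prints:

```
channel neighborhood: 9 centers; time neighborhood: 5 centers; crossed: 45 centers
accuracy map: 1 sample x 45 features (dims ['chan', 'time'])
accuracy range: [0.83, 1.00]  (chance = 1/3)
```

The crossed neighborhood has one center per (combined gradiometer, time
point) pair — 9 × 5 = 45 — and each map entry is the leave-one-chunk-out
decoding accuracy of the local channel/time window.  Values far above the
1/3 chance level reflect the condition-specific patterns planted by the
generator.  Group-level maps from several participants can then go through
`montecarlo_cluster_stat` (see `examples/06_group_cluster_stat.py`), which
reported `max z = 2.88` inside a planted 10-feature cluster with all nine
significant features inside it.

A thin command-line layer wires the same pipelines for shell use:

```sh
mvlight searchlight --input glm_maps.nii --targets 1,2,1,2 --chunks 1,1,2,2 \
    --measure crossvalidation --neighborhood spherical:count=100 \
    --output accuracy.nii
mvlight clusterstat --input group.plds --niter 1000 --tails 1 --output z.plds
```

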