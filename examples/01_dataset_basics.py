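"""The uniform dataset container: slicing, stacking, dimension reshaping.

Builds a tiny channel-by-time M/EEG dataset, selects a region of interest,
splits and re-merges it by acquisition chunk, and round-trips between the
flat samples-by-features matrix and the dense multi-dimensional array.
"""

import numpy as np

import mvlight as mv

ds = mv.make_toy_meeg(seed=0)
print(f"dataset: {ds.n_samples} samples x {ds.n_features} features")
print(f"feature dimensions: {ds.a.fdim.labels} "
      f"({len(ds.a.fdim.values['chan'])} channels x "
      f"{len(ds.a.fdim.values['time'])} time points)")
print("violations:", mv.validate_dataset(ds))

# feature selection: keep only the first two time bins
early = np.asarray(ds.fa["time"]) <= 2
roi = mv.slice_dataset(ds, early, axis="features")
print(f"early-time ROI: {roi.n_features} features")

# split into chunks and re-merge
chunks = np.asarray(ds.sa["chunks"])
parts = [mv.slice_dataset(ds, chunks == c, "samples")
         for c in np.unique(chunks)]
merged = mv.stack(parts, axis="samples")
print(f"split into {len(parts)} chunk groups, merged back to "
      f"{merged.n_samples} samples")

# unflatten to samples x chan x time and back
arr, labels, values = mv.unflatten(ds)
print(f"dense array shape: {arr.shape} (labels {labels})")
back = mv.flatten(arr, labels, values)
print("flatten(unflatten(ds)) identical samples:",
      np.array_equal(back.samples, ds.samples))

# move time onto the sample axis (used for time generalization)
moved = mv.dim_transpose(ds, "time", "samples")
print(f"after dim_transpose: {moved.n_samples} samples x "
      f"{moved.n_features} features; sample dims {moved.a.sdim.labels}")
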