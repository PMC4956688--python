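"""Uniform dataset container for multivariate pattern analysis.

A :class:`Dataset` holds a samples-by-features matrix together with
per-sample attributes (``sa``), per-feature attributes (``fa``) and general
attributes (``a``).  The same container represents volumetric fMRI data
(features are voxels), M/EEG channel/time data (features are channel-time
bins), searchlight output maps, and dissimilarity structures.

Dimension bookkeeping
---------------------
Multi-dimensional feature (or sample) spaces are described by a
:class:`DimensionList` stored in ``a.fdim`` (``a.sdim``).  For every
dimension label ``L`` there is a column ``fa[L]`` (``sa[L]``) holding
**1-based** positions into ``a.fdim.values[L]``.  The 1-based convention is
used throughout the attribute tables; plain Python/numpy indices into the
samples matrix (slice selectors, neighbor lists) are 0-based.

When a dense dataset is flattened, the **first** dimension label varies
fastest along the feature axis (Fortran-style enumeration of the grid), so
that reshaping round-trips are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DimensionList",
    "VolumeGeometry",
    "DatasetAttrs",
    "Dataset",
    "validate_dataset",
    "slice_dataset",
    "stack",
    "flatten",
    "unflatten",
    "dim_transpose",
    "dim_rename",
    "chunkize",
    "randomize_targets",
    "normalize",
]


@dataclass
class DimensionList:
    """Ordered dimension labels with their coordinate value lists."""

    labels: list[str]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = {k: np.asarray(v) for k, v in self.values.items()}

    def sizes(self) -> list[int]:
        return [len(self.values[label]) for label in self.labels]

    def copy(self) -> "DimensionList":
        return DimensionList(list(self.labels),
                             {k: v.copy() for k, v in self.values.items()})

    def equals(self, other: "DimensionList | None") -> bool:
        if other is None or self.labels != other.labels:
            return False
        for label in self.labels:
            a, b = self.values[label], other.values[label]
            if a.shape != b.shape:
                return False
            if a.dtype.kind in "US" or b.dtype.kind in "US":
                if not np.array_equal(a.astype(str), b.astype(str)):
                    return False
            elif not np.allclose(a.astype(float), b.astype(float), equal_nan=True):
                return False
        return True


@dataclass
class VolumeGeometry:
    """Affine grid geometry: ``mat`` maps 1-based voxel (i,j,k) to world mm."""

    mat: np.ndarray
    dim: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.mat = np.asarray(self.mat, dtype=float)
        self.dim = tuple(int(d) for d in self.dim)

    def copy(self) -> "VolumeGeometry":
        return VolumeGeometry(self.mat.copy(), self.dim)

    def equals(self, other: "VolumeGeometry | None") -> bool:
        return (other is not None and self.dim == other.dim
                and np.allclose(self.mat, other.mat))


@dataclass
class DatasetAttrs:
    """General dataset attributes: dimension descriptors, volume geometry, metadata."""

    fdim: DimensionList | None = None
    sdim: DimensionList | None = None
    vol: VolumeGeometry | None = None
    meta: dict = field(default_factory=dict)

    def copy(self) -> "DatasetAttrs":
        return DatasetAttrs(
            fdim=self.fdim.copy() if self.fdim is not None else None,
            sdim=self.sdim.copy() if self.sdim is not None else None,
            vol=self.vol.copy() if self.vol is not None else None,
            meta=dict(self.meta),
        )

    def equals(self, other: "DatasetAttrs") -> bool:
        for mine, theirs in ((self.fdim, other.fdim), (self.sdim, other.sdim)):
            if (mine is None) != (theirs is None):
                return False
            if mine is not None and not mine.equals(theirs):
                return False
        if (self.vol is None) != (other.vol is None):
            return False
        if self.vol is not None and not self.vol.equals(other.vol):
            return False
        return True


def _as_table(table, n: int, what: str) -> pd.DataFrame:
    if table is None:
        return pd.DataFrame(index=pd.RangeIndex(n))
    if isinstance(table, pd.DataFrame):
        df = table.reset_index(drop=True)
    else:
        df = pd.DataFrame({k: np.asarray(v) for k, v in dict(table).items()})
    if len(df) != n and len(df.columns) > 0:
        raise ValueError(f"{what} has {len(df)} rows, expected {n}")
    if len(df.columns) == 0:
        df = pd.DataFrame(index=pd.RangeIndex(n))
    return df


class Dataset:
    """Samples-by-features data matrix with sample/feature/general attributes.

    Parameters
    ----------
    samples:
        2-D numeric array, ``n_samples x n_features``.  NaN allowed.
    sa:
        Per-sample attribute table (mapping or DataFrame).  Reserved columns:
        ``targets`` (integer condition label) and ``chunks`` (integer
        independence group, e.g. acquisition run).
    fa:
        Per-feature attribute table.  Dimension-index columns are 1-based.
    a:
        :class:`DatasetAttrs` (``fdim``, ``sdim``, ``vol``, free-form ``meta``).
    """

    def __init__(self, samples, sa=None, fa=None, a: DatasetAttrs | None = None):
        self.samples = np.atleast_2d(np.asarray(samples))
        self.sa = _as_table(sa, self.samples.shape[0], "sa")
        self.fa = _as_table(fa, self.samples.shape[1], "fa")
        self.a = a if a is not None else DatasetAttrs()

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_features(self) -> int:
        return self.samples.shape[1]

    def copy(self) -> "Dataset":
        return Dataset(self.samples.copy(), self.sa.copy(), self.fa.copy(),
                       self.a.copy())

    def equals(self, other: "Dataset") -> bool:
        """Exact structural equality (NaN == NaN)."""
        if self.samples.shape != other.samples.shape:
            return False
        if not np.array_equal(self.samples, other.samples, equal_nan=True):
            return False
        for mine, theirs in ((self.sa, other.sa), (self.fa, other.fa)):
            if list(mine.columns) != list(theirs.columns):
                return False
            for col in mine.columns:
                a = np.asarray(mine[col])
                b = np.asarray(theirs[col])
                if a.dtype.kind in "USO" or b.dtype.kind in "USO":
                    if not np.array_equal(a.astype(str), b.astype(str)):
                        return False
                elif not np.array_equal(a.astype(float), b.astype(float),
                                        equal_nan=True):
                    return False
        return self.a.equals(other.a)

    def __repr__(self) -> str:  # pragma: no cover
        dims = ""
        if self.a.fdim is not None:
            dims = " fdim=" + "x".join(self.a.fdim.labels)
        return (f"<Dataset {self.n_samples}x{self.n_features}"
                f" sa={list(self.sa.columns)}{dims}>")


# ---------------------------------------------------------------------------
# validation

def validate_dataset(ds: Dataset) -> list[str]:
    """Check all structural invariants; return a list of violation messages.

    An empty list means the dataset is well formed.  Never raises.
    """
    out: list[str] = []
    if ds.samples.ndim != 2:
        out.append(f"samples: expected 2-D matrix, got ndim={ds.samples.ndim}")
        return out
    ns, nf = ds.samples.shape
    for col in ds.sa.columns:
        if len(ds.sa[col]) != ns:
            out.append(f"sa.{col}: length {len(ds.sa[col])} != n_samples {ns}")
    for col in ds.fa.columns:
        if len(ds.fa[col]) != nf:
            out.append(f"fa.{col}: length {len(ds.fa[col])} != n_features {nf}")

    for dim, table, axis_name in ((ds.a.fdim, ds.fa, "fa"),
                                  (ds.a.sdim, ds.sa, "sa")):
        if dim is None:
            continue
        if len(dim.labels) != len(set(dim.labels)):
            out.append(f"a.{'fdim' if axis_name == 'fa' else 'sdim'}: "
                       "duplicate dimension labels")
        for label in dim.labels:
            vals = dim.values.get(label)
            if vals is None or len(vals) == 0:
                out.append(f"dimension {label}: empty or missing value list")
                continue
            if len(np.unique(vals)) != len(vals):
                out.append(f"dimension {label}: value list entries not unique")
            if label not in table.columns:
                out.append(f"{axis_name}.{label}: missing index column for "
                           f"dimension label {label}")
                continue
            idx = np.asarray(table[label])
            if not np.issubdtype(idx.dtype, np.number):
                out.append(f"{axis_name}.{label}: non-numeric dimension indices")
                continue
            if np.any(idx != np.round(idx)):
                out.append(f"{axis_name}.{label}: non-integer dimension indices")
            if idx.size and (idx.min() < 1 or idx.max() > len(vals)):
                out.append(f"{axis_name}.{label}: indices outside [1, {len(vals)}] "
                           "(dimension indices are 1-based)")
    if ds.a.vol is not None:
        vol = ds.a.vol
        if vol.mat.shape != (4, 4):
            out.append("a.vol.mat: not a 4x4 matrix")
        elif abs(np.linalg.det(vol.mat[:3, :3])) < 1e-12:
            out.append("a.vol.mat: singular affine")
        if len(vol.dim) != 3 or any(d < 1 for d in vol.dim):
            out.append("a.vol.dim: needs 3 positive integers")
        if ds.a.fdim is not None:
            for label, d in zip(("i", "j", "k"), vol.dim):
                if label in ds.a.fdim.values and \
                        len(ds.a.fdim.values[label]) != d:
                    out.append(f"a.vol.dim: size mismatch with fdim.{label}")
    return out


# ---------------------------------------------------------------------------
# slicing / stacking

def _resolve_selector(selector, n: int, axis: str) -> np.ndarray:
    sel = np.asarray(selector)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ValueError(f"boolean mask length {sel.shape} does not match "
                             f"{axis} axis length {n}")
        return np.flatnonzero(sel)
    sel = sel.astype(int).ravel()
    if sel.size and (sel.min() < 0 or sel.max() >= n):
        raise IndexError(f"selector index out of range for {axis} axis "
                         f"of length {n}")
    return sel


def slice_dataset(ds: Dataset, selector, axis: str = "samples") -> Dataset:
    """Select samples (rows) or features (columns) by index list or boolean mask.

    The sliced axis's attribute table is subset in selector order; the other
    axis and the general attributes pass through unchanged.
    """
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    if axis == "samples":
        idx = _resolve_selector(selector, ds.n_samples, axis)
        return Dataset(ds.samples[idx, :].copy(),
                       ds.sa.iloc[idx].reset_index(drop=True),
                       ds.fa.copy(), ds.a.copy())
    idx = _resolve_selector(selector, ds.n_features, axis)
    return Dataset(ds.samples[:, idx].copy(), ds.sa.copy(),
                   ds.fa.iloc[idx].reset_index(drop=True), ds.a.copy())


def _tables_equal(a: pd.DataFrame, b: pd.DataFrame) -> str | None:
    """Return the name of the first mismatching column, or None if equal."""
    if list(a.columns) != list(b.columns):
        extra = set(a.columns) ^ set(b.columns)
        return sorted(extra)[0] if extra else a.columns[0]
    for col in a.columns:
        x, y = np.asarray(a[col]), np.asarray(b[col])
        if x.shape != y.shape:
            return col
        if x.dtype.kind in "USO" or y.dtype.kind in "USO":
            if not np.array_equal(x.astype(str), y.astype(str)):
                return col
        elif not np.array_equal(x.astype(float), y.astype(float), equal_nan=True):
            return col
    return None


def stack(parts: Sequence[Dataset], axis: str = "samples") -> Dataset:
    """Concatenate datasets along samples or features.

    For ``axis='samples'`` all parts must share identical feature attributes
    and general attributes; symmetrically for ``axis='features'``.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("cannot stack an empty list of datasets")
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    first = parts[0]
    for p in parts[1:]:
        if not first.a.equals(p.a):
            raise ValueError("dataset attributes (a) differ between stacked parts")
    if axis == "samples":
        for p in parts[1:]:
            bad = _tables_equal(first.fa, p.fa)
            if bad is not None:
                raise ValueError(f"feature attribute mismatch in column {bad!r}")
        samples = np.concatenate([p.samples for p in parts], axis=0)
        sa = pd.concat([p.sa for p in parts], ignore_index=True)
        return Dataset(samples, sa, first.fa.copy(), first.a.copy())
    for p in parts[1:]:
        bad = _tables_equal(first.sa, p.sa)
        if bad is not None:
            raise ValueError(f"sample attribute mismatch in column {bad!r}")
    samples = np.concatenate([p.samples for p in parts], axis=1)
    fa = pd.concat([p.fa for p in parts], ignore_index=True)
    return Dataset(samples, first.sa.copy(), fa, first.a.copy())


# ---------------------------------------------------------------------------
# flatten / unflatten

def _grid_indices(shape: Sequence[int]) -> np.ndarray:
    """1-based index grid, first dimension varying fastest; (n_cells, ndim)."""
    grids = np.meshgrid(*[np.arange(1, s + 1) for s in shape], indexing="ij")
    return np.stack([g.ravel(order="F") for g in grids], axis=1)


def flatten(array, labels: Sequence[str], values, axis: str = "features",
            sa=None, fa=None, a: DatasetAttrs | None = None) -> Dataset:
    """Build a Dataset from a dense multi-dimensional array.

    For ``axis='features'`` the array is ``n_samples x d1 x ... x dk`` where
    ``di`` matches ``len(values[labels[i]])``; features are enumerated with
    the first label varying fastest and 1-based index columns are written
    into ``fa``.  For ``axis='samples'`` the array is ``d1 x ... x dk x
    n_features`` and the index columns go into ``sa``.
    """
    arr = np.asarray(array)
    labels = list(labels)
    values = {k: np.asarray(v) for k, v in dict(values).items()}
    sizes = [len(values[label]) for label in labels]
    att = a.copy() if a is not None else DatasetAttrs()
    if axis == "features":
        if arr.shape[1:] != tuple(sizes):
            raise ValueError(f"array shape {arr.shape[1:]} does not match "
                             f"dimension sizes {sizes}")
        n = arr.shape[0]
        samples = arr.reshape(n, -1, order="F")
        grid = _grid_indices(sizes)
        fa_df = _as_table(fa, samples.shape[1], "fa")
        for col, label in enumerate(labels):
            fa_df[label] = grid[:, col]
        att.fdim = DimensionList(labels, values)
        return Dataset(samples, sa, fa_df, att)
    if axis == "samples":
        if arr.shape[:-1] != tuple(sizes):
            raise ValueError(f"array shape {arr.shape[:-1]} does not match "
                             f"dimension sizes {sizes}")
        nf = arr.shape[-1]
        samples = arr.reshape(-1, nf, order="F")
        grid = _grid_indices(sizes)
        sa_df = _as_table(sa, samples.shape[0], "sa")
        for col, label in enumerate(labels):
            sa_df[label] = grid[:, col]
        att.sdim = DimensionList(labels, values)
        return Dataset(samples, sa_df, fa, att)
    raise ValueError("axis must be 'samples' or 'features'")


def unflatten(ds: Dataset, axis: str = "features", fill: float = np.nan):
    """Expand a Dataset into a dense array along its fdim (or sdim) grid.

    Returns ``(array, labels, values)``.  For ``axis='features'`` the array is
    ``n_samples x d1 x ... x dk``; for ``axis='samples'`` it is
    ``d1 x ... x dk x n_features``.  Grid positions not present in the
    dataset receive ``fill``; duplicate assignments raise.
    """
    dim = ds.a.fdim if axis == "features" else ds.a.sdim
    if dim is None:
        raise ValueError(f"dataset has no {'fdim' if axis == 'features' else 'sdim'}")
    table = ds.fa if axis == "features" else ds.sa
    sizes = dim.sizes()
    idx_cols = [np.asarray(table[label]).astype(int) - 1 for label in dim.labels]
    flat_pos = np.ravel_multi_index(idx_cols, sizes, order="F") \
        if sizes else np.zeros(len(table), dtype=int)
    if len(np.unique(flat_pos)) != len(flat_pos):
        raise ValueError("duplicate grid position: dataset maps two "
                         "entries to the same dimension coordinates")
    ncells = int(np.prod(sizes))
    if axis == "features":
        out = np.full((ds.n_samples, ncells), fill, dtype=float)
        out[:, flat_pos] = ds.samples
        arr = out.reshape([ds.n_samples] + sizes, order="F")
    else:
        out = np.full((ncells, ds.n_features), fill, dtype=float)
        out[flat_pos, :] = ds.samples
        arr = out.reshape(sizes + [ds.n_features], order="F")
    return arr, list(dim.labels), {k: v.copy() for k, v in dim.values.items()}


# ---------------------------------------------------------------------------
# dimension moves

def dim_transpose(ds: Dataset, labels, target_axis: str) -> Dataset:
    """Move dimension labels between the feature and sample axes.

    The dataset must be dense in the moved labels: every combination of a
    moved-label position with the remaining positions on its axis occurs
    exactly once.  Moving a label to ``samples`` turns every (row, position)
    pair into a distinct sample, with the moved position varying slowest;
    symmetrically for ``features``.
    """
    if isinstance(labels, str):
        labels = [labels]
    labels = list(labels)
    if target_axis not in ("samples", "features"):
        raise ValueError("target_axis must be 'samples' or 'features'")
    source_axis = "features" if target_axis == "samples" else "samples"
    src_dim = ds.a.fdim if source_axis == "features" else ds.a.sdim
    if src_dim is None or any(lb not in src_dim.labels for lb in labels):
        missing = [lb for lb in labels
                   if src_dim is None or lb not in src_dim.labels]
        raise ValueError(f"label(s) {missing} not on the {source_axis} axis")
    src_table = ds.fa if source_axis == "features" else ds.sa
    keep_labels = [lb for lb in src_dim.labels if lb not in labels]

    moved_sizes = [len(src_dim.values[lb]) for lb in labels]
    moved_idx = np.stack([np.asarray(src_table[lb]).astype(int) - 1
                          for lb in labels], axis=1)
    moved_pos = np.ravel_multi_index(list(moved_idx.T), moved_sizes, order="F") \
        if labels else np.zeros(len(src_table), dtype=int)
    n_moved = int(np.prod(moved_sizes))

    # group source-axis entries by their remaining attribute signature
    other_cols = [c for c in src_table.columns if c not in labels]
    if other_cols:
        keys = pd.MultiIndex.from_frame(src_table[other_cols].astype(str))
    else:
        keys = pd.Index(np.zeros(len(src_table), dtype=int))
    group_codes, group_keys = pd.factorize(keys, sort=False)
    n_groups = len(group_keys)

    # placement[pos, group] -> source entry index; must be a bijection
    placement = np.full((n_moved, n_groups), -1, dtype=int)
    for entry, (p, g) in enumerate(zip(moved_pos, group_codes)):
        if placement[p, g] != -1:
            raise ValueError("dataset not dense in moved labels: duplicate "
                             "(position, remainder) combination")
        placement[p, g] = entry
    if np.any(placement < 0):
        raise ValueError("dataset not dense in moved labels: missing "
                         "(position, remainder) combination")

    group_rep = np.zeros(n_groups, dtype=int)  # representative source entry
    group_rep[group_codes] = np.arange(len(group_codes))

    a = ds.a.copy()
    moved_values = {lb: src_dim.values[lb].copy() for lb in labels}
    new_src_dim = DimensionList(keep_labels,
                                {lb: src_dim.values[lb].copy()
                                 for lb in keep_labels}) if keep_labels else None

    if source_axis == "features":
        # features -> samples: new sample (pos, old_row); pos varies slowest
        n_rows = ds.n_samples
        new_samples = np.empty((n_moved * n_rows, n_groups),
                               dtype=ds.samples.dtype)
        for p in range(n_moved):
            new_samples[p * n_rows:(p + 1) * n_rows, :] = \
                ds.samples[:, placement[p, :]]
        sa = pd.concat([ds.sa] * n_moved, ignore_index=True)
        grid = _grid_indices(moved_sizes)
        for col, lb in enumerate(labels):
            sa[lb] = np.repeat(grid[:, col], n_rows)
        fa = src_table.iloc[group_rep].reset_index(drop=True)
        fa = fa.drop(columns=labels)
        a.fdim = new_src_dim
        tgt = a.sdim
        tgt_labels = (list(tgt.labels) if tgt else []) + labels
        tgt_values = {**({k: v.copy() for k, v in tgt.values.items()} if tgt else {}),
                      **moved_values}
        a.sdim = DimensionList(tgt_labels, tgt_values)
        return Dataset(new_samples, sa, fa, a)

    # samples -> features: new feature (pos, old_col); pos varies slowest
    n_cols = ds.n_features
    new_samples = np.empty((n_groups, n_moved * n_cols), dtype=ds.samples.dtype)
    for p in range(n_moved):
        new_samples[:, p * n_cols:(p + 1) * n_cols] = \
            ds.samples[placement[p, :], :]
    fa = pd.concat([ds.fa] * n_moved, ignore_index=True)
    grid = _grid_indices(moved_sizes)
    for col, lb in enumerate(labels):
        fa[lb] = np.repeat(grid[:, col], n_cols)
    sa = src_table.iloc[group_rep].reset_index(drop=True)
    sa = sa.drop(columns=labels)
    a.sdim = new_src_dim
    tgt = a.fdim
    tgt_labels = (list(tgt.labels) if tgt else []) + labels
    tgt_values = {**({k: v.copy() for k, v in tgt.values.items()} if tgt else {}),
                  **moved_values}
    a.fdim = DimensionList(tgt_labels, tgt_values)
    return Dataset(new_samples, sa, fa, a)


def dim_rename(ds: Dataset, old_label: str, new_label: str) -> Dataset:
    """Rename a dimension label (and its index column) on either axis."""
    out = ds.copy()
    for dim, table_name in ((out.a.fdim, "fa"), (out.a.sdim, "sa")):
        if dim is not None and old_label in dim.labels:
            table = getattr(out, table_name)
            all_labels = set(out.fa.columns) | set(out.sa.columns)
            if out.a.fdim is not None:
                all_labels |= set(out.a.fdim.labels)
            if out.a.sdim is not None:
                all_labels |= set(out.a.sdim.labels)
            if new_label in all_labels:
                raise ValueError(f"label {new_label!r} already in use")
            dim.labels[dim.labels.index(old_label)] = new_label
            dim.values[new_label] = dim.values.pop(old_label)
            setattr(out, table_name,
                    table.rename(columns={old_label: new_label}))
            return out
    raise ValueError(f"dimension label {old_label!r} not found on either axis")


# ---------------------------------------------------------------------------
# chunk / target helpers

def chunkize(ds: Dataset, nchunks: int) -> np.ndarray:
    """Re-assign chunks into ``nchunks`` balanced groups (values 1..nchunks).

    Unique chunk values are sorted ascending and dealt round-robin into the
    output groups, so samples sharing an original chunk stay together and
    group sizes (counted in original chunks) differ by at most one.
    Deterministic: a pure function of the chunk values.
    """
    if "chunks" not in ds.sa.columns:
        raise ValueError("sa.chunks is required")
    chunks = np.asarray(ds.sa["chunks"])
    uniq = np.unique(chunks)
    if nchunks < 1 or len(uniq) < nchunks:
        raise ValueError(f"need at least {nchunks} unique chunks, "
                         f"found {len(uniq)}")
    mapping = {c: (i % nchunks) + 1 for i, c in enumerate(uniq)}
    return np.array([mapping[c] for c in chunks], dtype=int)


def randomize_targets(ds: Dataset, seed: int) -> np.ndarray:
    """Permute targets within each chunk; deterministic given ``seed``.

    Preserves the per-chunk multiset of target labels, so the permuted
    labels respect the independence structure of the data.
    """
    for col in ("targets", "chunks"):
        if col not in ds.sa.columns:
            raise ValueError(f"sa.{col} is required")
    rng = np.random.default_rng(seed)
    targets = np.asarray(ds.sa["targets"]).copy()
    chunks = np.asarray(ds.sa["chunks"])
    for c in np.unique(chunks):
        idx = np.flatnonzero(chunks == c)
        targets[idx] = targets[idx][rng.permutation(len(idx))]
    return targets


# ---------------------------------------------------------------------------
# normalization

def normalize(ds: Dataset, method: str = "zscore", axis: str = "samples",
              params: dict | None = None):
    """De-mean or z-score along an axis; returns ``(dataset, params)``.

    ``axis='samples'`` computes statistics across samples (per feature);
    ``axis='features'`` across features (per sample).  ``params`` returned
    from one call can be passed back to apply the identical transform to new
    data — the train/test pattern for cross-validated normalization.
    z-scoring uses the sample standard deviation (ddof=1); zero-variance
    entries produce NaN with a warning so they can be masked downstream.
    """
    if method not in ("demean", "zscore"):
        raise ValueError("method must be 'demean' or 'zscore'")
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    np_axis = 0 if axis == "samples" else 1
    if params is not None:
        if params.get("method") != method or params.get("axis") != axis:
            raise ValueError("params were estimated with different settings")
        mu = params["mean"]
        sd = params.get("std")
        expected = ds.n_features if axis == "samples" else ds.n_samples
        if np.asarray(mu).size != expected:
            raise ValueError("params length does not match the data")
    else:
        mu = np.nanmean(ds.samples, axis=np_axis, keepdims=True)
        sd = None
        if method == "zscore":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sd = np.nanstd(ds.samples, axis=np_axis, ddof=1, keepdims=True)
    mu = np.asarray(mu, dtype=float).reshape(
        (1, -1) if axis == "samples" else (-1, 1))
    out = ds.samples.astype(float) - mu
    if method == "zscore":
        sd = np.asarray(sd, dtype=float).reshape(mu.shape)
        if np.any(sd == 0):
            warnings.warn("zero-variance entries z-scored to NaN",
                          RuntimeWarning, stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = out / sd
            out[np.broadcast_to(sd == 0, out.shape)] = np.nan
    new_params = {"method": method, "axis": axis, "mean": mu.ravel().copy()}
    if method == "zscore":
        new_params["std"] = sd.ravel().copy()
    return Dataset(out, ds.sa.copy(), ds.fa.copy(), ds.a.copy()), new_params
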