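"""Dataset I/O: NIfTI volumes, a portable HDF5 container, channel layouts, TSV export.

The volume reader/writer keeps the affine convention used throughout the
package: ``a.vol.mat`` maps **1-based** voxel indices (i, j, k) to world mm.
NIfTI stores a 0-based affine, so reading applies a unit index shift and
writing reverses it; the shift is exactly symmetric so round trips are
bit-exact on mapped voxels.

The portable container (extension ``.plds``) is an HDF5 file holding the
samples matrix, the sa/fa attribute tables (one dataset per column), the
dimension descriptors and the volume geometry.  It is the package's
interchange format for channel/time data that NIfTI cannot represent.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import (Dataset, DatasetAttrs, DimensionList, VolumeGeometry,
                      flatten, unflatten)

__all__ = [
    "ChannelLayout",
    "read_fmri_volume",
    "write_fmri_volume",
    "save_container",
    "load_container",
    "load_layout",
    "available_layouts",
    "export_table",
]

CONTAINER_VERSION = 1

_SHIFT_TO_0BASED = np.array([[1, 0, 0, -1],
                             [0, 1, 0, -1],
                             [0, 0, 1, -1],
                             [0, 0, 0, 1]], dtype=float)
_SHIFT_TO_1BASED = np.linalg.inv(_SHIFT_TO_0BASED)


@dataclass
class ChannelLayout:
    """2-D sensor layout: channel ids, planar coordinates, kind, location group.

    ``kind`` is ``planar``, ``combined`` or ``eeg``; planar gradiometer pairs
    share a ``group_id`` with the combined channel at the same location.
    """

    name: str
    table: pd.DataFrame  # columns: channel_id, x, y, kind, group_id

    def __post_init__(self) -> None:
        ids = list(self.table["channel_id"])
        if len(ids) != len(set(ids)):
            raise ValueError(f"layout {self.name!r}: duplicate channel ids")
        combined_groups = set(
            self.table.loc[self.table["kind"] == "combined", "group_id"])
        for _, row in self.table[self.table["kind"] == "planar"].iterrows():
            if row["group_id"] not in combined_groups:
                raise ValueError(
                    f"layout {self.name!r}: planar channel "
                    f"{row['channel_id']!r} has no combined channel")


# ---------------------------------------------------------------------------
# NIfTI

def read_fmri_volume(path, mask=None, targets=None, chunks=None) -> Dataset:
    """Load a 3-D or 4-D NIfTI volume as a Dataset (one sample per volume).

    Features are the voxels where ``mask`` is nonzero (all voxels without a
    mask), enumerated with the i index varying fastest.  ``fa`` carries
    1-based (i, j, k) columns; ``a.vol.mat`` holds the affine adjusted to
    1-based indices.  Optional ``targets``/``chunks`` vectors are copied
    into ``sa``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError(f"expected a 3-D or 4-D volume, got ndim={data.ndim}")
    dim = data.shape[:3]
    n_samples = data.shape[3]
    mat = np.asarray(img.affine, dtype=float) @ _SHIFT_TO_0BASED

    # samples x (i fastest) voxels
    samples = data.reshape(-1, n_samples, order="F").T
    values = {lb: np.arange(1, d + 1) for lb, d in zip("ijk", dim)}
    arr = samples.reshape((n_samples,) + dim, order="F")
    ds = flatten(arr, ["i", "j", "k"], values, axis="features")
    ds.a.vol = VolumeGeometry(mat, dim)

    if mask is not None:
        mimg = nib.load(str(mask))
        mdata = np.asarray(mimg.dataobj)
        if mdata.shape[:3] != dim:
            raise ValueError(f"mask grid {mdata.shape[:3]} does not match "
                             f"data grid {dim}")
        keep = mdata.reshape(-1, order="F") != 0
        from .dataset import slice_dataset
        ds = slice_dataset(ds, keep, axis="features")

    if targets is not None:
        ds.sa["targets"] = np.asarray(targets)
    if chunks is not None:
        ds.sa["chunks"] = np.asarray(chunks)
    return ds


def write_fmri_volume(ds: Dataset, path, fill: float = 0.0) -> None:
    """Write a volumetric Dataset to NIfTI (3-D if one sample, else 4-D).

    Voxels not present in the dataset receive ``fill``.  The stored affine
    undoes the 1-based index shift so a read/write round trip recovers the
    original affine exactly.
    """
    if ds.a.vol is None or ds.a.fdim is None or \
            any(lb not in ds.a.fdim.labels for lb in "ijk"):
        raise ValueError("dataset needs i,j,k feature dimensions and a.vol")
    arr, labels, _ = unflatten(ds, axis="features", fill=fill)
    # arr: n_samples x di x dj x dk in fdim label order; reorder to i,j,k
    order = [labels.index(lb) for lb in "ijk"]
    arr = np.moveaxis(arr, [1 + o for o in order], [1, 2, 3])
    vol = np.moveaxis(arr, 0, -1)  # i,j,k,n
    if vol.shape[-1] == 1:
        vol = vol[..., 0]
    affine = ds.a.vol.mat @ _SHIFT_TO_1BASED
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine),
             str(path))


# ---------------------------------------------------------------------------
# portable container

def _write_array(group, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    if arr.dtype.kind in "USO":
        dt = h5py.string_dtype(encoding="utf-8")
        group.create_dataset(name, data=arr.astype(str).astype(object),
                             dtype=dt, track_times=False)
    else:
        group.create_dataset(name, data=arr, track_times=False)


def _read_array(node) -> np.ndarray:
    arr = node[()]
    if arr.dtype.kind in "OS":
        arr = np.asarray([x.decode() if isinstance(x, bytes) else str(x)
                          for x in arr.ravel()]).reshape(arr.shape)
    return arr


def _write_str_list(group, name: str, items: list[str]) -> None:
    group.attrs.create(name, data=np.asarray(items, dtype=object),
                       dtype=h5py.string_dtype(encoding="utf-8"))


def _write_table(group, df: pd.DataFrame) -> None:
    _write_str_list(group, "columns", [str(c) for c in df.columns])
    group.attrs["n"] = len(df)
    for col in df.columns:
        _write_array(group, str(col), np.asarray(df[col]))


def _read_table(group) -> pd.DataFrame:
    cols = [c.decode() if isinstance(c, bytes) else str(c)
            for c in group.attrs["columns"]]
    n = int(group.attrs["n"])
    data = {c: _read_array(group[c]) for c in cols}
    df = pd.DataFrame(data)
    if len(df.columns) == 0:
        df = pd.DataFrame(index=pd.RangeIndex(n))
    return df


def _write_dim(group, dim: DimensionList) -> None:
    _write_str_list(group, "labels", dim.labels)
    vals = group.create_group("values")
    for label in dim.labels:
        _write_array(vals, label, dim.values[label])


def _read_dim(group) -> DimensionList:
    labels = [x.decode() if isinstance(x, bytes) else str(x)
              for x in group.attrs["labels"]]
    values = {lb: _read_array(group["values"][lb]) for lb in labels}
    return DimensionList(labels, values)


def save_container(ds: Dataset, path) -> None:
    """Save a Dataset to the portable ``.plds`` container (lossless)."""
    with h5py.File(str(path), "w", track_order=True) as f:
        f.attrs["format"] = "plds"
        f.attrs["version"] = CONTAINER_VERSION
        f.create_dataset("samples", data=np.asarray(ds.samples, dtype=float),
                         track_times=False)
        _write_table(f.create_group("sa"), ds.sa)
        _write_table(f.create_group("fa"), ds.fa)
        a = f.create_group("a")
        if ds.a.fdim is not None:
            _write_dim(a.create_group("fdim"), ds.a.fdim)
        if ds.a.sdim is not None:
            _write_dim(a.create_group("sdim"), ds.a.sdim)
        if ds.a.vol is not None:
            vol = a.create_group("vol")
            vol.create_dataset("mat", data=ds.a.vol.mat, track_times=False)
            vol.create_dataset("dim", data=np.asarray(ds.a.vol.dim),
                               track_times=False)


def load_container(path) -> Dataset:
    """Load a Dataset from a ``.plds`` container written by :func:`save_container`."""
    with h5py.File(str(path), "r") as f:
        if f.attrs.get("format") not in ("plds", b"plds"):
            raise ValueError(f"{path}: not a plds container")
        version = int(f.attrs.get("version", -1))
        if version != CONTAINER_VERSION:
            raise ValueError(f"{path}: unsupported container version {version}")
        if "samples" not in f:
            raise ValueError(f"{path}: container is missing the samples matrix")
        samples = f["samples"][()]
        sa = _read_table(f["sa"])
        fa = _read_table(f["fa"])
        a = DatasetAttrs()
        if "a" in f:
            if "fdim" in f["a"]:
                a.fdim = _read_dim(f["a"]["fdim"])
            if "sdim" in f["a"]:
                a.sdim = _read_dim(f["a"]["sdim"])
            if "vol" in f["a"]:
                a.vol = VolumeGeometry(f["a"]["vol"]["mat"][()],
                                       tuple(f["a"]["vol"]["dim"][()]))
    return Dataset(samples, sa, fa, a)


# ---------------------------------------------------------------------------
# channel layouts

def available_layouts() -> list[str]:
    root = importlib.resources.files("mvlight") / "resources" / "layouts"
    return sorted(p.name[:-4] for p in root.iterdir() if p.name.endswith(".tsv"))


def load_layout(name: str) -> ChannelLayout:
    """Load a built-in channel layout by name (e.g. ``toy9``, ``grid_eeg_16``)."""
    root = importlib.resources.files("mvlight") / "resources" / "layouts"
    path = root / f"{name}.tsv"
    if not path.is_file():
        raise ValueError(f"unknown layout {name!r}; available: "
                         f"{', '.join(available_layouts())}")
    with path.open("r") as fh:
        table = pd.read_csv(fh, sep="\t",
                            dtype={"channel_id": str, "kind": str,
                                   "group_id": str})
    return ChannelLayout(name=name, table=table)


# ---------------------------------------------------------------------------
# TSV export

def export_table(ds: Dataset, path) -> None:
    """Export a dataset with at most two feature dimensions as TSV text.

    One row per feature: the dimension coordinate values followed by one
    column per sample (``value`` for a single sample, else ``value1..N``).
    """
    if ds.a.fdim is None or len(ds.a.fdim.labels) > 2:
        raise ValueError("export_table supports at most 2 feature dimensions")
    cols: dict[str, np.ndarray] = {}
    for label in ds.a.fdim.labels:
        idx = np.asarray(ds.fa[label]).astype(int) - 1
        cols[label] = np.asarray(ds.a.fdim.values[label])[idx]
    if ds.n_samples == 1:
        cols["value"] = ds.samples[0]
    else:
        for s in range(ds.n_samples):
            cols[f"value{s + 1}"] = ds.samples[s]
    df = pd.DataFrame(cols)
    df.to_csv(str(path), sep="\t", index=False, float_format="%.12g")
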