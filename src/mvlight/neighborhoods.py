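"""Generalized neighborhoods: the geometry of searchlight analyses.

A :class:`Neighborhood` maps every *center* in an output feature space to a
list of feature indices (0-based) in the input dataset.  Centers can live in
voxel space (spherical neighborhoods), along a time or frequency axis
(interval neighborhoods), over sensor locations (channel neighborhoods), or
in the Cartesian product of several such spaces (crossed neighborhoods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dataset import Dataset, DatasetAttrs, DimensionList

__all__ = [
    "Neighborhood",
    "spherical_neighborhood",
    "interval_neighborhood",
    "channel_neighborhood",
    "cross_neighborhood",
]


@dataclass
class Neighborhood:
    """Per-center input-feature index lists plus the output feature space.

    ``neighbors[c]`` holds 0-based indices into the input dataset's feature
    axis.  ``fa``/``a`` describe the output space (one entry per center) and
    become the feature attributes of a searchlight map.  ``origin`` records
    the input space for compatibility checks.
    """

    neighbors: list[np.ndarray]
    fa: pd.DataFrame
    a: DatasetAttrs
    origin: dict = field(default_factory=dict)

    @property
    def n_centers(self) -> int:
        return len(self.neighbors)

    def validate(self, n_input_features: int | None = None) -> list[str]:
        out = []
        n_in = n_input_features if n_input_features is not None \
            else self.origin.get("n_features")
        for c, nb in enumerate(self.neighbors):
            nb = np.asarray(nb)
            if nb.size and (nb.min() < 0 or (n_in is not None
                                             and nb.max() >= n_in)):
                out.append(f"center {c}: neighbor index out of range")
        for col in self.fa.columns:
            if len(self.fa[col]) != self.n_centers:
                out.append(f"fa.{col}: length != n_centers")
        if self.a.fdim is not None:
            for label in self.a.fdim.labels:
                if label not in self.fa.columns:
                    out.append(f"fa.{label}: missing column for fdim label")
        return out


def _world_coords(ds: Dataset) -> np.ndarray:
    """World-mm coordinates of every feature via the 1-based voxel affine."""
    ijk = np.stack([np.asarray(ds.fa[lb]).astype(float) for lb in "ijk"]
                   + [np.ones(ds.n_features)], axis=0)
    return (ds.a.vol.mat @ ijk)[:3].T


def spherical_neighborhood(ds: Dataset, radius: float | None = None,
                           count: int | None = None) -> Neighborhood:
    """Voxel neighborhoods with a fixed radius (mm) or a fixed voxel count.

    One center per input feature.  Radius mode selects all features within
    ``radius`` mm (closed ball, world coordinates); count mode grows the
    radius until exactly ``count`` features are selected, breaking distance
    ties by feature index so results are platform-independent.  A fixed
    count equalizes pattern sizes between locations near tissue boundaries
    and interior locations.
    """
    if (radius is None) == (count is None):
        raise ValueError("exactly one of radius/count must be given")
    if ds.a.vol is None or ds.a.fdim is None or \
            any(lb not in ds.a.fdim.labels for lb in "ijk"):
        raise ValueError("dataset needs i,j,k feature dimensions and a.vol")
    xyz = _world_coords(ds)
    n = ds.n_features
    tree = cKDTree(xyz)
    neighbors: list[np.ndarray] = []
    if radius is not None:
        if radius < 0:
            raise ValueError("radius must be non-negative")
        balls = tree.query_ball_point(xyz, r=radius + 1e-9)
        for c, ball in enumerate(balls):
            idx = np.asarray(sorted(ball), dtype=int)
            d = np.linalg.norm(xyz[idx] - xyz[c], axis=1)
            order = np.lexsort((idx, d))
            neighbors.append(idx[order])
    else:
        if not 1 <= count <= n:
            raise ValueError(f"count must be in [1, {n}]")
        dk, _ = tree.query(xyz, k=count)
        kth = dk[:, -1] if count > 1 else dk.ravel()
        for c in range(n):
            ball = tree.query_ball_point(xyz[c], r=kth[c] + 1e-9)
            idx = np.asarray(sorted(ball), dtype=int)
            d = np.linalg.norm(xyz[idx] - xyz[c], axis=1)
            order = np.lexsort((idx, d))
            neighbors.append(idx[order][:count])
    return Neighborhood(neighbors=neighbors, fa=ds.fa.copy(), a=ds.a.copy(),
                        origin={"n_features": n,
                                "fdim_labels": list(ds.a.fdim.labels)})


def interval_neighborhood(ds: Dataset, label: str,
                          radius: int = 0) -> Neighborhood:
    """Neighborhoods along one feature dimension (time or frequency bins).

    One center per position of ``label``; a center at position ``p``
    collects **all** features whose ``label`` index falls within
    ``[p - radius, p + radius]`` (truncated at the axis boundaries),
    across every other dimension.  Radius 0 keeps only the center bin.
    The output space has ``label`` as its single dimension.
    """
    if ds.a.fdim is None or label not in ds.a.fdim.labels:
        raise ValueError(f"unknown feature dimension label {label!r}")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    pos = np.asarray(ds.fa[label]).astype(int)  # 1-based
    npos = len(ds.a.fdim.values[label])
    neighbors = []
    for p in range(1, npos + 1):
        mask = (pos >= p - radius) & (pos <= p + radius)
        neighbors.append(np.flatnonzero(mask))
    fa = pd.DataFrame({label: np.arange(1, npos + 1)})
    a = DatasetAttrs(fdim=DimensionList(
        [label], {label: ds.a.fdim.values[label].copy()}))
    return Neighborhood(neighbors=neighbors, fa=fa, a=a,
                        origin={"n_features": ds.n_features,
                                "fdim_labels": list(ds.a.fdim.labels)})


def channel_neighborhood(ds: Dataset, layout, count: int | None = None,
                         radius: float | None = None,
                         chantype: str = "same") -> Neighborhood:
    """Sensor-space neighborhoods from a 2-D channel layout.

    ``chantype='same'`` centers on the dataset's own channels;
    ``chantype='combined_from_planar'`` centers on combined gradiometers
    while selecting the underlying planar gradiometer pairs, so output maps
    carry one value per sensor location but patterns use the raw planar
    data.  A center selects the ``count`` nearest sensor locations (or all
    within ``radius``, layout units) by planar 2-D distance; its neighbor
    features are all features — every time/frequency bin — whose channel
    sits at a selected location.
    """
    from .io import ChannelLayout  # local import to avoid a cycle

    if (radius is None) == (count is None):
        raise ValueError("exactly one of radius/count must be given")
    if ds.a.fdim is None or "chan" not in ds.a.fdim.labels:
        raise ValueError("dataset needs a 'chan' feature dimension")
    if not isinstance(layout, ChannelLayout):
        raise TypeError("layout must be a ChannelLayout")
    ds_channels = [str(c) for c in ds.a.fdim.values["chan"]]
    missing = [c for c in ds_channels if c not in set(layout.table["channel_id"])]
    if missing:
        raise ValueError(f"channels missing from layout {layout.name!r}: "
                         f"{missing[:5]}")

    tab = layout.table
    if chantype == "combined_from_planar":
        centers_tab = tab[tab["kind"] == "combined"].reset_index(drop=True)
    elif chantype == "same":
        centers_tab = tab[tab["channel_id"].isin(ds_channels)]
        centers_tab = centers_tab.set_index("channel_id") \
            .loc[ds_channels].reset_index()
    else:
        raise ValueError("chantype must be 'same' or 'combined_from_planar'")

    coords = centers_tab[["x", "y"]].to_numpy(dtype=float)
    n_loc = len(centers_tab)
    if count is not None and not 1 <= count <= n_loc:
        raise ValueError(f"count must be in [1, {n_loc}]")

    chan_pos = np.asarray(ds.fa["chan"]).astype(int)  # 1-based into ds channels
    chan_name_by_pos = {p + 1: ds_channels[p] for p in range(len(ds_channels))}
    # feature indices per channel name
    feats_by_chan: dict[str, np.ndarray] = {}
    for name in set(ds_channels):
        pos_ids = [p for p, nm in chan_name_by_pos.items() if nm == name]
        feats_by_chan[name] = np.flatnonzero(np.isin(chan_pos, pos_ids))

    neighbors = []
    for c in range(n_loc):
        d = np.linalg.norm(coords - coords[c], axis=1)
        if count is not None:
            order = np.lexsort((np.arange(n_loc), d))
            sel = order[:count]
        else:
            sel = np.flatnonzero(d <= radius + 1e-9)
        chans: list[str] = []
        for loc in sel:
            if chantype == "combined_from_planar":
                grp = centers_tab.iloc[loc]["group_id"]
                planar_ids = [ch for ch in (tab[(tab["kind"] == "planar") &
                                                (tab["group_id"] == grp)]
                                            ["channel_id"])]
                chans.extend(ch for ch in planar_ids if ch in feats_by_chan)
            else:
                ch = centers_tab.iloc[loc]["channel_id"]
                if ch in feats_by_chan:
                    chans.append(ch)
        idx = np.unique(np.concatenate(
            [feats_by_chan[ch] for ch in chans])) if chans \
            else np.array([], dtype=int)
        neighbors.append(idx)

    out_names = np.asarray(centers_tab["channel_id"], dtype=str)
    fa = pd.DataFrame({"chan": np.arange(1, n_loc + 1)})
    a = DatasetAttrs(fdim=DimensionList(["chan"], {"chan": out_names}))
    return Neighborhood(neighbors=neighbors, fa=fa, a=a,
                        origin={"n_features": ds.n_features,
                                "fdim_labels": list(ds.a.fdim.labels)})


def cross_neighborhood(ds: Dataset,
                       parts: list[Neighborhood]) -> Neighborhood:
    """Cartesian product of neighborhoods; neighbor sets intersect.

    Centers enumerate the product of the parts' centers with the FIRST
    part's centers varying fastest.  A crossed center's neighbors are the
    intersection of its parts' neighbor sets; empty intersections are kept
    (the searchlight reports NaN there).  Output dimensions concatenate the
    parts' dimensions, which must not share labels.
    """
    if not parts:
        raise ValueError("need at least one neighborhood to cross")
    n_in = ds.n_features
    labels: list[str] = []
    for p in parts:
        if p.origin.get("n_features") != n_in:
            raise ValueError("neighborhood origin does not match the dataset")
        if p.a.fdim is not None:
            for lb in p.a.fdim.labels:
                if lb in labels:
                    raise ValueError(f"duplicate output dimension label {lb!r}")
                labels.append(lb)

    masks = [np.stack([np.isin(np.arange(n_in), nb) for nb in p.neighbors])
             for p in parts]
    counts = [p.n_centers for p in parts]
    # first part varies fastest
    grids = np.meshgrid(*[np.arange(c) for c in counts], indexing="ij")
    combo = np.stack([g.ravel(order="F") for g in grids], axis=1)

    neighbors = []
    for row in combo:
        m = masks[0][row[0]].copy()
        for k in range(1, len(parts)):
            m &= masks[k][row[k]]
        neighbors.append(np.flatnonzero(m))

    fa_cols = {}
    for k, p in enumerate(parts):
        sub = p.fa.iloc[combo[:, k]].reset_index(drop=True)
        for col in sub.columns:
            fa_cols[col] = np.asarray(sub[col])
    values = {}
    for p in parts:
        if p.a.fdim is not None:
            for lb in p.a.fdim.labels:
                values[lb] = p.a.fdim.values[lb].copy()
    a = DatasetAttrs(fdim=DimensionList(labels, values))
    return Neighborhood(neighbors=neighbors, fa=pd.DataFrame(fa_cols), a=a,
                        origin={"n_features": n_in,
                                "fdim_labels": parts[0].origin.get("fdim_labels")})
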