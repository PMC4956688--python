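"""Cluster-level inference: TFCE, clustering, and Monte-Carlo FWE correction.

Threshold-free cluster enhancement (TFCE) integrates cluster extent and
height over all thresholds,

    TFCE(f) = sum_{h = dh, 2dh, ... <= max} e(f, h)^E * h^H * dh,

where ``e(f, h)`` is the size of the suprathreshold (map >= h) connected
component containing feature f under a given adjacency.  This removes the
arbitrary cluster-forming threshold of fixed-threshold correction.  Negative
map values are enhanced on the negated map and re-negated.

Group-level family-wise error (FWE) control uses the permutation
distribution of the maximum statistic across features: per iteration the
participant maps are sign-flipped around the null mean (or resampled from
per-participant null maps), the feature-wise one-sample t map is
re-enhanced, and its maximum is recorded.  A feature's corrected p-value is
the fraction of iterations whose maximum reaches its observed enhanced
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtri

from .dataset import Dataset
from .neighborhoods import Neighborhood

__all__ = [
    "ClusterStatResult",
    "feature_adjacency",
    "tfce_transform",
    "find_clusters",
    "montecarlo_cluster_stat",
]

_T_CAP = 50.0  # cap for degenerate zero-variance t values


# ---------------------------------------------------------------------------
# adjacency

def feature_adjacency(ds: Dataset, layout=None,
                      chan_radius: float | None = None) -> Neighborhood:
    """Automatic feature adjacency from the dataset's dimensions.

    Two features are adjacent when they differ by at most one index step in
    every feature dimension: voxels get 26-connectivity, time/frequency bins
    connect to their immediate neighbors, and channels connect to layout
    locations within ``chan_radius`` (default: 1.5 x the smallest nonzero
    inter-location distance, which on a square grid includes diagonals).
    Crossed dimensions combine by conjunction.  Each feature is its own
    neighbor.
    """
    if ds.a.fdim is None or not ds.a.fdim.labels:
        raise ValueError("dataset needs feature dimensions (a.fdim)")
    nf = ds.n_features
    adj = np.ones((nf, nf), dtype=bool)
    for label in ds.a.fdim.labels:
        pos = np.asarray(ds.fa[label]).astype(int) - 1
        npos = len(ds.a.fdim.values[label])
        if label == "chan":
            if layout is None:
                raise ValueError("channel dimension requires a layout for "
                                 "adjacency")
            names = [str(c) for c in ds.a.fdim.values["chan"]]
            tab = layout.table.set_index("channel_id")
            coords = np.array([[tab.loc[c, "x"], tab.loc[c, "y"]]
                               for c in names], dtype=float)
            dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :],
                                  axis=2)
            if chan_radius is None:
                nz = dmat[dmat > 0]
                chan_radius = 1.5 * nz.min() if nz.size else 0.0
            pos_adj = dmat <= chan_radius + 1e-9
        else:
            steps = np.abs(np.arange(npos)[:, None] - np.arange(npos)[None, :])
            pos_adj = steps <= 1
        adj &= pos_adj[pos[:, None], pos[None, :]]
    neighbors = [np.flatnonzero(adj[f]) for f in range(nf)]
    return Neighborhood(neighbors=neighbors, fa=ds.fa.copy(), a=ds.a.copy(),
                        origin={"n_features": nf,
                                "fdim_labels": list(ds.a.fdim.labels)})


def _adjacency_csr(nbrhood: Neighborhood, n: int):
    """Neighbor lists -> (indptr, indices) CSR arrays (self-links removed)."""
    indptr = np.zeros(n + 1, dtype=np.int64)
    chunks = []
    for f in range(n):
        nb = np.asarray(nbrhood.neighbors[f], dtype=np.int64)
        nb = nb[nb != f]
        chunks.append(nb)
        indptr[f + 1] = indptr[f] + len(nb)
    indices = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
    return indptr, indices


# ---------------------------------------------------------------------------
# TFCE kernel: descending-threshold union-find

def _tfce_kernel_py(values, indptr, indices, E, H, dh):
    n = values.shape[0]
    vmax = 0.0
    for i in range(n):
        if values[i] > vmax:
            vmax = values[i]
    out = np.zeros(n)
    if vmax < dh:
        return out
    n_lev = int(np.floor(vmax / dh + 1e-12))

    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    order = np.argsort(-values, kind="stable").astype(np.int64)
    stamp = np.full(n, -1, dtype=np.int64)
    inc = np.zeros(n)
    ptr = 0

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for lev in range(n_lev, 0, -1):
        h = lev * dh
        while ptr < n and values[order[ptr]] >= h:
            x = order[ptr]
            ptr += 1
            parent[x] = x
            size[x] = 1
            for t in indices[indptr[x]:indptr[x + 1]]:
                if parent[t] != -1:
                    rx, rt = find(x), find(t)
                    if rx != rt:
                        if size[rx] < size[rt]:
                            rx, rt = rt, rx
                        parent[rt] = rx
                        size[rx] += size[rt]
        add = (h ** H) * dh
        for q in range(ptr):
            i = order[q]
            r = find(i)
            if stamp[r] != lev:
                stamp[r] = lev
                inc[r] = (size[r] ** E) * add
            out[i] += inc[r]
    return out


try:  # optional jit; the pure-Python kernel is the reference behavior
    from numba import njit as _njit

    @_njit(cache=False)
    def _tfce_kernel_nb(values, indptr, indices, E, H, dh):  # pragma: no cover
        n = values.shape[0]
        vmax = 0.0
        for i in range(n):
            if values[i] > vmax:
                vmax = values[i]
        out = np.zeros(n)
        if vmax < dh:
            return out
        n_lev = int(np.floor(vmax / dh + 1e-12))
        parent = np.full(n, -1, dtype=np.int64)
        size = np.zeros(n, dtype=np.int64)
        order = np.argsort(-values, kind="mergesort").astype(np.int64)
        stamp = np.full(n, -1, dtype=np.int64)
        inc = np.zeros(n)
        ptr = 0
        for lev in range(n_lev, 0, -1):
            h = lev * dh
            while ptr < n and values[order[ptr]] >= h:
                x = order[ptr]
                ptr += 1
                parent[x] = x
                size[x] = 1
                for jj in range(indptr[x], indptr[x + 1]):
                    t = indices[jj]
                    if parent[t] != -1:
                        rx = x
                        while parent[rx] != rx:
                            rx = parent[rx]
                        rt = t
                        while parent[rt] != rt:
                            rt = parent[rt]
                        if rx != rt:
                            if size[rx] < size[rt]:
                                tmp = rx
                                rx = rt
                                rt = tmp
                            parent[rt] = rx
                            size[rx] += size[rt]
            add = (h ** H) * dh
            for q in range(ptr):
                i = order[q]
                r = i
                while parent[r] != r:
                    r = parent[r]
                parent[i] = r
                if stamp[r] != lev:
                    stamp[r] = lev
                    inc[r] = (size[r] ** E) * add
                out[i] += inc[r]
        return out

    _tfce_kernel = _tfce_kernel_nb
except Exception:  # pragma: no cover
    _tfce_kernel = _tfce_kernel_py


def tfce_transform(map_values, adjacency: Neighborhood, E: float = 0.5,
                   H: float = 2.0, dh: float = 0.1) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    Positive and negative parts are enhanced separately (the negative part
    on the negated map) and recombined with sign; zeros map to zero.
    Defaults E=0.5, H=2, dh=0.1 are the standard TFCE parameters.
    """
    v = np.asarray(map_values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("map must be finite")
    if dh <= 0:
        raise ValueError("dh must be positive")
    indptr, indices = _adjacency_csr(adjacency, len(v))
    return _tfce_signed(v, indptr, indices, E, H, dh)


def _tfce_signed(v, indptr, indices, E, H, dh):
    out = np.zeros_like(v)
    if np.any(v > 0):
        out += _tfce_kernel(np.maximum(v, 0.0), indptr, indices,
                            float(E), float(H), float(dh))
    if np.any(v < 0):
        out -= _tfce_kernel(np.maximum(-v, 0.0), indptr, indices,
                            float(E), float(H), float(dh))
    return out


# ---------------------------------------------------------------------------
# fixed-threshold clustering

def find_clusters(map_values, threshold: float, adjacency: Neighborhood):
    """Connected components of ``map >= threshold``; returns (clusters, masses).

    ``clusters`` is a list of feature-index arrays; ``mass`` sums the
    suprathreshold map values of each cluster.
    """
    v = np.asarray(map_values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("map must be finite")
    above = np.flatnonzero(v >= threshold)
    if above.size == 0:
        return [], np.zeros(0)
    indptr, indices = _adjacency_csr(adjacency, len(v))
    sub = {f: i for i, f in enumerate(above)}
    rows, cols = [], []
    for f in above:
        for t in indices[indptr[f]:indptr[f + 1]]:
            if t in sub:
                rows.append(sub[f])
                cols.append(sub[t])
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(above.size, above.size))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [above[labels == c] for c in range(n_comp)]
    masses = np.array([v[cl].sum() for cl in clusters])
    return clusters, masses


def _cluster_mass_map(v, threshold, indptr, indices, n):
    """Per-feature cluster mass for v >= threshold (0 below threshold)."""
    out = np.zeros(n)
    above = np.flatnonzero(v >= threshold)
    if above.size == 0:
        return out
    # flood fill over the suprathreshold subgraph
    seen = np.zeros(n, dtype=bool)
    above_mask = np.zeros(n, dtype=bool)
    above_mask[above] = True
    for start in above:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            f = stack.pop()
            comp.append(f)
            for t in indices[indptr[f]:indptr[f + 1]]:
                if above_mask[t] and not seen[t]:
                    seen[t] = True
                    stack.append(t)
        comp = np.asarray(comp)
        out[comp] = v[comp].sum()
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo group statistics

@dataclass
class ClusterStatResult:
    """Group-level z map with its null distribution metadata.

    ``z`` is a 1 x n_features Dataset of signed z scores over the input
    feature space; ``p`` holds the FWE-corrected per-feature p values;
    ``p_uncorrected`` the feature-wise (uncorrected) permutation p values;
    ``null_max`` the per-iteration maximum null statistics.
    """

    z: Dataset
    p: np.ndarray
    p_uncorrected: np.ndarray
    null_max: np.ndarray
    params: dict = field(default_factory=dict)


def _t_map(maps: np.ndarray, h0_mean: float) -> np.ndarray:
    n = maps.shape[0]
    diff = maps - h0_mean
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate] = np.sign(mean[degenerate]) * _T_CAP
    return t


def montecarlo_cluster_stat(group_ds: Dataset, adjacency: Neighborhood,
                            niter: int = 1000, h0_mean: float = 0.0,
                            method: str = "sign_flip",
                            null_maps: list | None = None,
                            cluster_stat: str = "tfce",
                            threshold: float | None = None,
                            tails: int = 2, seed: int | None = None,
                            E: float = 0.5, H: float = 2.0,
                            dh: float = 0.1) -> ClusterStatResult:
    """Group-level cluster-corrected z map via the max-statistic permutation.

    ``group_ds`` holds one map per participant (rows).  The observed
    statistic is the feature-wise one-sample t against ``h0_mean``, passed
    through TFCE (or fixed-threshold cluster mass).  Null iterations either
    sign-flip each participant's map around ``h0_mean`` (``sign_flip``) or
    draw one map per participant from ``null_maps`` with replacement
    (``null_map_sampling``).  FWE-corrected p values come from the
    distribution of the per-iteration maximum statistic; z is the inverse
    standard normal of 1 - p (one-tailed) or 1 - p/2 with the effect's sign
    (two-tailed), with p clamped to [1/(niter+1), 1 - 1/(niter+1)] so z
    stays finite.  Deterministic given ``seed``.
    """
    if niter < 1:
        raise ValueError("niter must be >= 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    maps = np.asarray(group_ds.samples, dtype=float)
    n_part, n_feat = maps.shape
    if n_part < 2:
        raise ValueError("need at least 2 participants")
    if method not in ("sign_flip", "null_map_sampling"):
        raise ValueError("method must be 'sign_flip' or 'null_map_sampling'")
    if method == "null_map_sampling":
        if null_maps is None or len(null_maps) != n_part:
            raise ValueError("null_map_sampling needs one list of null maps "
                             "per participant")
        null_maps = [np.atleast_2d(np.asarray(m, dtype=float))
                     for m in null_maps]
        for m in null_maps:
            if m.shape[1] != n_feat or m.shape[0] < 1:
                raise ValueError("each participant needs >= 1 null map with "
                                 f"{n_feat} features")
    if cluster_stat not in ("tfce", "fixed"):
        raise ValueError("cluster_stat must be 'tfce' or 'fixed'")
    if cluster_stat == "fixed" and threshold is None:
        raise ValueError("fixed-threshold clustering needs a threshold")

    indptr, indices = _adjacency_csr(adjacency, n_feat)

    def stat_map(t: np.ndarray) -> np.ndarray:
        if cluster_stat == "tfce":
            if tails == 1:
                return _tfce_kernel(np.maximum(t, 0.0), indptr, indices,
                                    float(E), float(H), float(dh))
            return _tfce_signed(t, indptr, indices, E, H, dh)
        pos = _cluster_mass_map(t, threshold, indptr, indices, n_feat)
        if tails == 1:
            return pos
        neg = _cluster_mass_map(-t, threshold, indptr, indices, n_feat)
        return pos - neg

    t_obs = _t_map(maps, h0_mean)
    s_obs = stat_map(t_obs)
    s_obs_mag = s_obs if tails == 1 else np.abs(s_obs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(niter)
    exceed = np.zeros(n_feat)          # FWE via max statistic
    exceed_fw = np.zeros(n_feat)       # feature-wise (uncorrected)
    for it in range(niter):
        if method == "sign_flip":
            flips = rng.integers(0, 2, size=n_part) * 2 - 1
            perm = h0_mean + flips[:, None] * (maps - h0_mean)
        else:
            draws = [m[rng.integers(0, m.shape[0])] for m in null_maps]
            perm = np.stack(draws)
        s_null = stat_map(_t_map(perm, h0_mean))
        s_mag = s_null if tails == 1 else np.abs(s_null)
        null_max[it] = s_mag.max() if n_feat else 0.0
        exceed += null_max[it] >= s_obs_mag
        exceed_fw += s_mag >= s_obs_mag

    p = (1.0 + exceed) / (niter + 1.0)
    p_fw = (1.0 + exceed_fw) / (niter + 1.0)
    p_min = 1.0 / (niter + 1.0)
    p_clamped = np.clip(p, p_min, 1.0 - p_min)
    if tails == 1:
        z = ndtri(1.0 - p_clamped)
    else:
        z = np.sign(s_obs) * ndtri(1.0 - p_clamped / 2.0)
    z[s_obs_mag == 0] = 0.0

    z_ds = Dataset(z.reshape(1, -1), None, group_ds.fa.copy(),
                   group_ds.a.copy())
    params = {"niter": niter, "seed": seed, "h0_mean": h0_mean,
              "method": method, "cluster_stat": cluster_stat,
              "threshold": threshold, "E": E, "H": H, "dh": dh,
              "tails": tails}
    return ClusterStatResult(z=z_ds, p=p, p_uncorrected=p_fw,
                             null_max=null_max, params=params)
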