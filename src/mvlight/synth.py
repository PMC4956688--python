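"""Deterministic synthetic datasets for tests, examples and calibration.

The generators emulate the *structure* of real neuroimaging data — layout,
dimensions, chunk/target bookkeeping, nominal effect sizes — with
independent Gaussian noise.  Class effects are injected as fixed per-class
mean patterns on a configurable feature subset, so decoding accuracy and
cluster recovery scale with ``effect_size`` and vanish at 0.  All
generators are pure functions of their options including the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import Dataset, DatasetAttrs, DimensionList, VolumeGeometry, \
    flatten
from .io import load_layout

__all__ = ["make_toy_meeg", "make_toy_fmri", "make_group_maps",
           "default_signal_region"]


def make_toy_meeg(n_targets: int = 3, n_chunks: int = 4,
                  layout: str = "toy9", n_time: int = 5, t0: float = 0.0,
                  dt: float = 0.1, effect_size: float = 1.0,
                  noise_sd: float = 1.0, n_repeats: int = 1,
                  signal_channels=None, signal_times=None,
                  seed: int = 0) -> Dataset:
    """Channel-by-time M/EEG dataset on a planar-gradiometer layout.

    Defaults give 18 planar channels (9 sensor-location pairs) x 5 time
    points from 0 to 0.4 s, 3 conditions x 4 chunks, ``n_repeats`` samples
    per condition and chunk.  Each condition has a fixed mean pattern of
    standard deviation ``effect_size`` injected on ``signal_channels`` x
    ``signal_times`` (defaults: all channels/times) on top of unit Gaussian
    noise.
    """
    lay = load_layout(layout)
    planar = lay.table[lay.table["kind"].isin(["planar", "eeg"])]
    channels = np.asarray(planar["channel_id"], dtype=str)
    n_chan = len(channels)
    times = t0 + dt * np.arange(n_time)

    rng = np.random.default_rng(seed)
    chan_sel = np.arange(n_chan) if signal_channels is None \
        else np.asarray(signal_channels, dtype=int)
    time_sel = np.arange(n_time) if signal_times is None \
        else np.asarray(signal_times, dtype=int)

    class_patterns = np.zeros((n_targets, n_chan, n_time))
    effect = rng.normal(0.0, 1.0, size=(n_targets, len(chan_sel),
                                        len(time_sel)))
    class_patterns[np.ix_(np.arange(n_targets), chan_sel, time_sel)] = \
        effect_size * effect

    n_samples = n_targets * n_chunks * n_repeats
    arr = np.empty((n_samples, n_chan, n_time))
    targets = np.empty(n_samples, dtype=int)
    chunks = np.empty(n_samples, dtype=int)
    row = 0
    for chunk in range(1, n_chunks + 1):
        for _rep in range(n_repeats):
            for t in range(1, n_targets + 1):
                arr[row] = class_patterns[t - 1] + \
                    rng.normal(0.0, noise_sd, size=(n_chan, n_time))
                targets[row] = t
                chunks[row] = chunk
                row += 1

    ds = flatten(arr, ["chan", "time"],
                 {"chan": channels, "time": times}, axis="features")
    ds.sa["targets"] = targets
    ds.sa["chunks"] = chunks
    return ds


def default_signal_region(dim) -> np.ndarray:
    """Centered cubic block of 1-based voxel indices (width <= 5, odd)."""
    width = min(5, min(int(d) for d in dim))
    if width % 2 == 0:
        width -= 1
    starts = [(int(d) - width) // 2 + 1 for d in dim]
    return np.array([(i, j, k)
                     for i in range(starts[0], starts[0] + width)
                     for j in range(starts[1], starts[1] + width)
                     for k in range(starts[2], starts[2] + width)])


def make_toy_fmri(dim=(10, 10, 10), voxel_mm: float = 3.0,
                  n_targets: int = 2, n_chunks: int = 4,
                  n_repeats: int = 6, signal_region=None,
                  effect_size: float = 1.0, noise_sd: float = 1.0,
                  taper_sigma: float = 1.5, seed: int = 0) -> Dataset:
    """Volumetric dataset with a focal class-dependent activation.

    ``signal_region`` is an (n, 3) array of 1-based (i, j, k) voxel indices;
    the default is a centered 5 x 5 x 5 block.  Class-mean patterns inside
    the region are scaled by a Gaussian falloff of width ``taper_sigma``
    voxels around the region centroid, emulating a focal activation with a
    well-defined peak rather than a flat-top block; voxels outside the
    region carry pure noise.  ``n_repeats`` samples are drawn per condition
    and chunk (run).  The affine is diagonal ``voxel_mm`` with a 1-based
    origin.
    """
    dim = tuple(int(d) for d in dim)
    if signal_region is None:
        signal_region = default_signal_region(dim)
    signal_region = np.asarray(signal_region, dtype=int)
    if signal_region.ndim != 2 or signal_region.shape[1] != 3:
        raise ValueError("signal_region must be an (n, 3) index array")
    if np.any(signal_region < 1) or np.any(signal_region > np.asarray(dim)):
        raise ValueError("signal_region outside the volume grid")

    rng = np.random.default_rng(seed)
    centroid = signal_region.mean(axis=0)
    taper = np.exp(-np.sum((signal_region - centroid) ** 2, axis=1)
                   / (2.0 * taper_sigma ** 2))

    class_means = np.zeros((n_targets,) + dim)
    region_ix = tuple((signal_region - 1).T)
    for t in range(n_targets):
        pat = rng.normal(0.0, 1.0, size=len(signal_region))
        class_means[t][region_ix] = effect_size * pat * taper

    n_samples = n_targets * n_chunks * n_repeats
    arr = np.empty((n_samples,) + dim)
    targets = np.empty(n_samples, dtype=int)
    chunks = np.empty(n_samples, dtype=int)
    row = 0
    for chunk in range(1, n_chunks + 1):
        for _rep in range(n_repeats):
            for t in range(1, n_targets + 1):
                arr[row] = class_means[t - 1] + \
                    rng.normal(0.0, noise_sd, size=dim)
                targets[row] = t
                chunks[row] = chunk
                row += 1

    values = {lb: np.arange(1, d + 1) for lb, d in zip("ijk", dim)}
    ds = flatten(arr, ["i", "j", "k"], values, axis="features")
    mat = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    ds.a.vol = VolumeGeometry(mat, dim)
    ds.sa["targets"] = targets
    ds.sa["chunks"] = chunks
    return ds


def make_group_maps(n_participants: int = 12, n_features: int = 100,
                    true_effect=None, noise_sd: float = 1.0,
                    seed: int = 0) -> Dataset:
    """Per-participant statistic maps: ``true_effect + Gaussian noise``.

    One row per participant (``chunks`` = participant index, ``targets`` =
    1) over a 1-D feature axis (dimension ``pos``), ready for
    :func:`~mvlight.cluster.montecarlo_cluster_stat`.
    """
    if true_effect is None:
        true_effect = np.zeros(n_features)
    true_effect = np.asarray(true_effect, dtype=float)
    if true_effect.size != n_features:
        raise ValueError("true_effect length must equal n_features")
    rng = np.random.default_rng(seed)
    samples = true_effect[None, :] + \
        rng.normal(0.0, noise_sd, size=(n_participants, n_features))
    sa = pd.DataFrame({"targets": np.ones(n_participants, dtype=int),
                       "chunks": np.arange(1, n_participants + 1)})
    fa = pd.DataFrame({"pos": np.arange(1, n_features + 1)})
    a = DatasetAttrs(fdim=DimensionList(
        ["pos"], {"pos": np.arange(1, n_features + 1)}))
    return Dataset(samples, sa, fa, a)
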