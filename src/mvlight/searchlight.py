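"""Searchlight engine: apply a measure at every neighborhood center.

For each center the input dataset is sliced to the center's neighbor
features, the measure is applied, and the single-column results are stacked
into an information map whose feature space is the neighborhood's output
space.  Centers are independent, so evaluation may be parallelized; results
are always assembled in center order regardless of scheduling.
"""

from __future__ import annotations

import warnings

import numpy as np

from .dataset import Dataset
from .neighborhoods import Neighborhood

__all__ = ["searchlight"]


def _eval_center(ds: Dataset, neighbors: np.ndarray, measure, opt: dict):
    from .dataset import slice_dataset
    if len(neighbors) == 0:
        return None
    sub = slice_dataset(ds, neighbors, axis="features")
    return measure(sub, **opt)


def searchlight(ds: Dataset, nbrhood: Neighborhood, measure,
                opt: dict | None = None, center_ids=None,
                n_workers: int = 1) -> Dataset:
    """Run ``measure`` at every (selected) neighborhood center.

    Parameters
    ----------
    ds:
        Input dataset; must have the feature space the neighborhood was
        built from.
    nbrhood:
        Maps centers to input-feature index lists and defines the output
        feature space.
    measure:
        Uniform-signature measure ``measure(ds, **opt) -> Dataset`` with a
        single samples column.
    opt:
        Keyword options forwarded to the measure.
    center_ids:
        Optional 0-based subset of centers to evaluate.
    n_workers:
        Number of parallel workers (joblib); results are identical for any
        worker count.

    Returns
    -------
    Dataset with one feature per evaluated center; feature attributes come
    from the neighborhood, sample attributes from the measure result.
    Centers with no neighbors yield an all-NaN column and a warning.
    """
    opt = dict(opt or {})
    n_in = nbrhood.origin.get("n_features")
    if n_in is not None and n_in != ds.n_features:
        raise ValueError(f"neighborhood was built for {n_in} features, "
                         f"dataset has {ds.n_features}")
    if center_ids is None:
        center_ids = np.arange(nbrhood.n_centers)
    else:
        center_ids = np.asarray(center_ids, dtype=int)
        if center_ids.size and (center_ids.min() < 0 or
                                center_ids.max() >= nbrhood.n_centers):
            raise IndexError("center id out of range")

    if n_workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_workers)(
            delayed(_eval_center)(ds, nbrhood.neighbors[c], measure, opt)
            for c in center_ids)
    else:
        results = []
        for c in center_ids:
            try:
                results.append(_eval_center(ds, nbrhood.neighbors[c],
                                            measure, opt))
            except Exception as exc:
                raise RuntimeError(
                    f"measure failed at center {c}: {exc}") from exc

    first = next((r for r in results if r is not None), None)
    if first is None:
        raise ValueError("all selected centers have empty neighborhoods")
    if first.samples.shape[1] != 1:
        raise ValueError("measure must return a single-column dataset, got "
                         f"{first.samples.shape[1]} columns")
    n_rows = first.samples.shape[0]

    out = np.full((n_rows, len(center_ids)), np.nan)
    n_empty = 0
    for col, res in enumerate(results):
        if res is None:
            n_empty += 1
            continue
        if res.samples.shape[0] != n_rows:
            raise ValueError(
                f"center {center_ids[col]} returned {res.samples.shape[0]} "
                f"rows, expected {n_rows}: measures must produce consistent "
                "output across centers")
        out[:, col] = res.samples[:, 0]
    if n_empty:
        warnings.warn(f"{n_empty} center(s) had no neighbors; their columns "
                      "are NaN", RuntimeWarning, stacklevel=2)

    a = nbrhood.a.copy()
    a.sdim = first.a.sdim.copy() if first.a.sdim is not None else None
    fa = nbrhood.fa.iloc[center_ids].reset_index(drop=True)
    return Dataset(out, first.sa.copy(), fa, a)
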