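"""MVPA measures: functions mapping a Dataset to a single-column result Dataset.

A *measure* has the uniform signature ``measure(ds, **opt) -> Dataset`` where
the result's ``samples`` is a column vector (possibly many rows) and ``sa``
(plus ``a.sdim``) describe what the rows mean.  This contract is what lets
the searchlight apply any measure at every neighborhood center and stack the
columns into an information map.

Provided measures: cross-validated classification (accuracy or per-sample
predictions), split-half correlation with Fisher z contrast, representational
similarity (correlation between a neural and a target dissimilarity matrix),
the raw pairwise dissimilarity matrix, and generalization across a sample
dimension (e.g. the train-time x test-time decoding matrix).
"""

from __future__ import annotations

import inspect
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .dataset import (Dataset, DatasetAttrs, DimensionList, chunkize,
                      normalize, slice_dataset)
from .learning import PartitionSet, check_partitions, classify_lda, \
    make_partitions

__all__ = [
    "crossvalidation_measure",
    "correlation_measure",
    "target_dsm_corr_measure",
    "dissimilarity_matrix_measure",
    "dim_generalization_measure",
]

_ATANH_CLAMP = 1.0 - 1e-15


def crossvalidation_measure(ds: Dataset, classifier=classify_lda,
                            partitions: PartitionSet | None = None,
                            output: str = "accuracy",
                            normalization: str | None = None,
                            classifier_opt: dict | None = None) -> Dataset:
    """Cross-validated classification accuracy or per-sample predictions.

    Per fold the classifier is trained on the train rows and predicts the
    test rows; with ``normalization`` ('demean' or 'zscore'), parameters are
    estimated on the training set only and applied to the test set.
    ``output='accuracy'`` pools correct predictions over all folds into a
    single value; ``output='predictions'`` returns one row per sample with
    its predicted label (the last fold's prediction if a sample is tested
    more than once; NaN if never tested).
    """
    if partitions is None:
        partitions = make_partitions(ds, "nfold")
    bad = check_partitions(partitions, ds)
    if bad:
        raise ValueError("invalid partitions: " + "; ".join(bad))
    if output not in ("accuracy", "predictions"):
        raise ValueError("output must be 'accuracy' or 'predictions'")
    targets = np.asarray(ds.sa["targets"])
    opt = dict(classifier_opt or {})

    n_correct = 0
    n_total = 0
    predicted = np.full(ds.n_samples, np.nan)
    for f, (train, test) in enumerate(partitions):
        X_train, X_test = ds.samples[train], ds.samples[test]
        if normalization is not None:
            tr_ds, params = normalize(Dataset(X_train), normalization,
                                      axis="samples")
            te_ds, _ = normalize(Dataset(X_test), normalization,
                                 axis="samples", params=params)
            X_train, X_test = tr_ds.samples, te_ds.samples
            keep = np.all(np.isfinite(X_train), axis=0) & \
                np.all(np.isfinite(X_test), axis=0)
            X_train, X_test = X_train[:, keep], X_test[:, keep]
        try:
            pred = classifier(X_train, targets[train], X_test, **opt)
        except Exception as exc:
            raise RuntimeError(f"classifier failed in fold {f}: {exc}") from exc
        pred = np.asarray(pred)
        n_correct += int(np.sum(pred == targets[test]))
        n_total += len(test)
        predicted[test] = pred

    if output == "accuracy":
        samples = np.array([[n_correct / n_total]])
        sa = pd.DataFrame({"label": ["accuracy"]})
        return Dataset(samples, sa, None, DatasetAttrs())
    sa = pd.DataFrame({"targets": targets})
    return Dataset(predicted.reshape(-1, 1), sa, None, DatasetAttrs())


def _half_means(ds: Dataset, half_mask: np.ndarray,
                targets_sorted: np.ndarray) -> np.ndarray:
    targets = np.asarray(ds.sa["targets"])
    means = []
    for t in targets_sorted:
        rows = half_mask & (targets == t)
        if not np.any(rows):
            raise ValueError(f"target {t} missing from one half")
        means.append(ds.samples[rows].mean(axis=0))
    return np.stack(means)


def _cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of A with each row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = Ac @ Bc.T
    den = np.sqrt((Ac ** 2).sum(axis=1))[:, None] * \
        np.sqrt((Bc ** 2).sum(axis=1))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlation_measure(ds: Dataset, split=None, weights=None) -> Dataset:
    """Split-half pattern-correlation contrast (Fisher-transformed).

    The samples are split into two independent halves (explicit ``split``
    masks, the two chunk values if there are exactly two, else chunks are
    re-grouped into two).  Per half and target a mean pattern is computed;
    ``C[i, j]`` is the Pearson correlation between target i's half-1 mean
    and target j's half-2 mean, and ``Z = atanh(C)``.  The result is
    ``sum(W * Z)`` averaged over both half orderings, with the default
    contrast W weighting the diagonal ``1/C_n`` and the off-diagonal
    ``-1/(C_n (C_n - 1))`` — mean within-target minus mean between-target
    correlation, positive when patterns are target-specific and reliable.
    """
    targets = np.asarray(ds.sa["targets"])
    targets_sorted = np.unique(targets)
    n_t = len(targets_sorted)
    if split is not None:
        half1, half2 = (np.asarray(h, dtype=bool) for h in split)
    else:
        if "chunks" not in ds.sa.columns:
            raise ValueError("sa.chunks required to derive split halves")
        uniq = np.unique(np.asarray(ds.sa["chunks"]))
        halves = np.asarray(ds.sa["chunks"]) if len(uniq) == 2 \
            else chunkize(ds, 2)
        hvals = np.unique(halves)
        half1, half2 = halves == hvals[0], halves == hvals[1]

    m1 = _half_means(ds, half1, targets_sorted)
    m2 = _half_means(ds, half2, targets_sorted)
    if weights is None:
        W = np.full((n_t, n_t), -1.0 / (n_t * (n_t - 1)))
        np.fill_diagonal(W, 1.0 / n_t)
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != (n_t, n_t):
            raise ValueError(f"weights must be {n_t}x{n_t}")

    result = 0.0
    for A, B in ((m1, m2), (m2, m1)):
        C = _cross_corr(A, B)
        if np.any(np.abs(C) > _ATANH_CLAMP):
            warnings.warn("correlation at |r|=1 clamped before Fisher "
                          "transform", RuntimeWarning, stacklevel=2)
        Z = np.arctanh(np.clip(C, -_ATANH_CLAMP, _ATANH_CLAMP))
        result += float(np.sum(W * Z))
    result /= 2.0
    sa = pd.DataFrame({"label": ["corr"]})
    return Dataset(np.array([[result]]), sa, None, DatasetAttrs())


def _neural_dsm_vector(samples: np.ndarray, metric: str) -> np.ndarray:
    if metric in ("correlation", "euclidean", "cosine", "cityblock",
                  "sqeuclidean", "chebyshev"):
        return pdist(samples, metric)
    raise ValueError(f"unknown dissimilarity metric {metric!r}")


def target_dsm_corr_measure(ds: Dataset, target_dsm,
                            metric: str = "correlation",
                            corr_type: str = "pearson") -> Dataset:
    """Representational similarity: correlate neural and target dissimilarities.

    The neural dissimilarity matrix holds pairwise distances (default
    1 - Pearson r) between the sample rows, one row per condition.  The
    result is the Pearson (or Spearman) correlation between the
    upper-triangle vectors of the neural and target matrices.
    """
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 condition patterns")
    tgt = np.asarray(target_dsm, dtype=float)
    if tgt.ndim == 2:
        if tgt.shape != (n, n):
            raise ValueError(f"target_dsm is {tgt.shape}, expected ({n}, {n})")
        if not np.allclose(tgt, tgt.T):
            raise ValueError("target_dsm must be symmetric")
        tgt_vec = squareform(tgt, checks=False)
    else:
        if tgt.size != n * (n - 1) // 2:
            raise ValueError("target_dsm vector length does not match "
                             f"{n} conditions")
        tgt_vec = tgt.ravel()
    neural = _neural_dsm_vector(np.asarray(ds.samples, dtype=float), metric)
    if corr_type == "pearson":
        rho = float(np.corrcoef(neural, tgt_vec)[0, 1])
    elif corr_type == "spearman":
        rho = float(spearmanr(neural, tgt_vec).statistic)
    else:
        raise ValueError("corr_type must be 'pearson' or 'spearman'")
    sa = pd.DataFrame({"label": ["rho"]})
    return Dataset(np.array([[rho]]), sa, None, DatasetAttrs())


def dissimilarity_matrix_measure(ds: Dataset,
                                 metric: str = "correlation") -> Dataset:
    """Pairwise dissimilarities between samples as a single-column dataset.

    Rows enumerate the upper triangle in pair order (1,2), (1,3), ...,
    (1,n), (2,3), ...; ``sa.targets1``/``sa.targets2`` give the 1-based
    condition indices of each pair, and ``a.sdim`` describes the pair grid
    so unflattening along samples yields the square matrix.
    """
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = _neural_dsm_vector(np.asarray(ds.samples, dtype=float), metric)
    pairs = np.array([(i + 1, j + 1) for i in range(n)
                      for j in range(i + 1, n)], dtype=int)
    if "targets" in ds.sa.columns:
        cond_values = np.asarray(ds.sa["targets"])
    else:
        cond_values = np.arange(1, n + 1)
    sa = pd.DataFrame({"targets1": pairs[:, 0], "targets2": pairs[:, 1]})
    sdim = DimensionList(["targets1", "targets2"],
                         {"targets1": cond_values.copy(),
                          "targets2": cond_values.copy()})
    return Dataset(d.reshape(-1, 1), sa, None, DatasetAttrs(sdim=sdim))


def dim_generalization_measure(ds: Dataset, dimension: str,
                               measure=None, radius: int = 0,
                               **measure_opt) -> Dataset:
    """Generalization across a sample dimension (e.g. time generalization).

    The input has ``dimension`` on the sample axis (moved there with
    :func:`~mvlight.dataset.dim_transpose`) and ``sa.chunks`` in {1, 2}
    marking the train (1) and test (2) halves.  For every pair of train and
    test positions, samples within ``radius`` positions of each center are
    gathered — window offsets become extra features — and the inner measure
    is applied with a single train/test fold.  Offsets are restricted to
    those in range for *both* centers so train and test feature spaces
    match at the boundaries.

    The output has one row per (train, test) position pair, with sample
    dimensions ``train_<dimension>`` and ``test_<dimension>`` (the train
    position varying fastest).
    """
    if measure is None:
        measure = crossvalidation_measure
    if ds.a.sdim is None or dimension not in ds.a.sdim.labels:
        raise ValueError(f"{dimension!r} must be a sample dimension "
                         "(use dim_transpose first)")
    chunks = np.asarray(ds.sa["chunks"])
    if not set(np.unique(chunks)) <= {1, 2}:
        raise ValueError("sa.chunks must be 1 (train) or 2 (test)")
    pos = np.asarray(ds.sa[dimension]).astype(int)  # 1-based
    dim_values = ds.a.sdim.values[dimension]
    train_pos = np.unique(pos[chunks == 1])
    test_pos = np.unique(pos[chunks == 2])

    accepts_partitions = "partitions" in \
        inspect.signature(measure).parameters

    def _window_dataset(center: int, offsets: np.ndarray,
                        chunk_val: int) -> tuple[np.ndarray, np.ndarray]:
        """Rows stacked over offsets: (n_rows x n_feat*|offsets|, targets)."""
        blocks = []
        targets_ref = None
        for o in offsets:
            rows = np.flatnonzero((chunks == chunk_val) & (pos == center + o))
            blocks.append(ds.samples[rows])
            t = np.asarray(ds.sa["targets"])[rows]
            if targets_ref is None:
                targets_ref = t
            elif not np.array_equal(targets_ref, t):
                raise ValueError("window positions have inconsistent sample "
                                 "structure (dataset not dense in "
                                 f"{dimension!r})")
        return np.concatenate(blocks, axis=1), targets_ref

    rows_out = []
    sa_train = []
    sa_test = []
    for ti, p_test in enumerate(test_pos):
        for p_train in train_pos:
            offsets = np.array(
                [o for o in range(-radius, radius + 1)
                 if (p_train + o in set(train_pos))
                 and (p_test + o in set(test_pos))], dtype=int)
            if offsets.size == 0:
                offsets = np.array([0])
            X_tr, y_tr = _window_dataset(p_train, offsets, 1)
            X_te, y_te = _window_dataset(p_test, offsets, 2)
            n_tr = X_tr.shape[0]
            combined = Dataset(
                np.concatenate([X_tr, X_te], axis=0),
                pd.DataFrame({
                    "targets": np.concatenate([y_tr, y_te]),
                    "chunks": np.concatenate([np.ones(n_tr, dtype=int),
                                              np.full(X_te.shape[0], 2)]),
                }))
            opt = dict(measure_opt)
            if accepts_partitions and "partitions" not in opt:
                opt["partitions"] = PartitionSet(folds=[
                    (np.arange(n_tr), np.arange(n_tr, combined.n_samples))])
            res = measure(combined, **opt)
            if res.samples.shape != (1, 1):
                raise ValueError("inner measure must return a single value "
                                 f"per pair, got shape {res.samples.shape}")
            rows_out.append(res.samples[0, 0])
            sa_train.append(int(np.flatnonzero(train_pos == p_train)[0]) + 1)
            sa_test.append(ti + 1)

    train_label = f"train_{dimension}"
    test_label = f"test_{dimension}"
    sa = pd.DataFrame({train_label: sa_train, test_label: sa_test})
    sdim = DimensionList(
        [train_label, test_label],
        {train_label: dim_values[train_pos - 1].copy(),
         test_label: dim_values[test_pos - 1].copy()})
    return Dataset(np.asarray(rows_out).reshape(-1, 1), sa, None,
                   DatasetAttrs(sdim=sdim))
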