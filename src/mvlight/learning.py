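"""Classifiers with a uniform signature and cross-validation partition schemes.

Every classifier is a plain function
``classifier(samples_train, targets_train, samples_test, **opt) -> predictions``
so measures and searchlights can swap classifiers freely.  The test targets
are never passed in, making it structurally impossible for a classifier to
peek at them.

Partition schemes operate on ``sa.chunks`` — integer labels marking groups
of statistically independent samples (e.g. acquisition runs) — and always
keep whole chunks on one side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .dataset import Dataset

__all__ = [
    "PartitionSet",
    "classify_lda",
    "classify_naive_bayes",
    "make_partitions",
    "check_partitions",
]


@dataclass
class PartitionSet:
    """Folds of (train_indices, test_indices) over samples (0-based)."""

    folds: list[tuple[np.ndarray, np.ndarray]]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


def _check_train(samples_train, targets_train, samples_test):
    X = np.asarray(samples_train, dtype=float)
    y = np.asarray(targets_train)
    T = np.atleast_2d(np.asarray(samples_test, dtype=float))
    if X.ndim != 2 or T.ndim != 2:
        raise ValueError("samples must be 2-D (n_samples x n_features)")
    if len(y) != X.shape[0]:
        raise ValueError("targets length does not match training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ValueError("classifier inputs must be finite (no NaN/inf)")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data needs at least 2 classes")
    return X, y, T, classes


def classify_lda(samples_train, targets_train, samples_test,
                 regularization: float = 0.01) -> np.ndarray:
    """Regularized linear discriminant analysis with equal class priors.

    Fits per-class means and the pooled within-class covariance
    ``S = (1/(n-C)) * sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)^T``,
    regularized as ``S_r = S + lambda * (trace(S)/p) * I`` so the problem
    stays well-posed when features outnumber samples (the typical
    searchlight regime).  Predicts
    ``argmax_c mu_c^T S_r^{-1} x - 0.5 mu_c^T S_r^{-1} mu_c``;
    ties go to the smallest class label.
    """
    X, y, T, classes = _check_train(samples_train, targets_train, samples_test)
    n, p = X.shape
    C = len(classes)
    mus = np.stack([X[y == c].mean(axis=0) for c in classes])
    S = np.zeros((p, p))
    for k, c in enumerate(classes):
        R = X[y == c] - mus[k]
        S += R.T @ R
    dof = max(n - C, 1)
    S /= dof
    lam = regularization * (np.trace(S) / p) if p else 0.0
    if lam <= 0:
        lam = regularization  # all-zero covariance: fall back to ridge on I
    S_r = S + lam * np.eye(p)
    W = np.linalg.solve(S_r, mus.T)            # p x C
    scores = T @ W - 0.5 * np.sum(mus.T * W, axis=0)  # n_test x C
    return classes[np.argmax(scores, axis=1)]


def classify_naive_bayes(samples_train, targets_train, samples_test,
                         var_floor: float = 1e-12) -> np.ndarray:
    """Gaussian naive Bayes with empirical class priors.

    Each feature is modelled as an independent Gaussian per class; variances
    are floored at ``var_floor`` so constant features stay finite.  Ties go
    to the smallest class label.
    """
    X, y, T, classes = _check_train(samples_train, targets_train, samples_test)
    log_scores = np.empty((T.shape[0], len(classes)))
    n = X.shape[0]
    for k, c in enumerate(classes):
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        var = np.maximum(Xc.var(axis=0), var_floor)
        log_prior = np.log(Xc.shape[0] / n)
        ll = -0.5 * (np.log(2 * np.pi * var) + (T - mu) ** 2 / var)
        log_scores[:, k] = log_prior + ll.sum(axis=1)
    return classes[np.argmax(log_scores, axis=1)]


# ---------------------------------------------------------------------------
# partitions

def make_partitions(ds: Dataset, scheme: str = "nfold", k: int = 2,
                    group_attr: str | None = None) -> PartitionSet:
    """Build cross-validation folds from chunk structure.

    Schemes
    -------
    ``nfold``
        One fold per unique chunk: test on it, train on the rest.
    ``oddeven``
        Two folds by odd/even *rank* of the sorted unique chunk values
        (robust to arbitrary chunk numbering).
    ``take_k_out``
        One fold per ``k``-combination of chunks (test on the combination).
    ``cross_grouped``
        Cross-decoding over ``group_attr`` (e.g. modality or participant):
        for every ordered pair of distinct group values (g_train, g_test)
        and every chunk c, train on group g_train excluding chunk c and
        test on group g_test restricted to chunk c.

    Folds are ordered deterministically (sorted chunk/group values).
    """
    if "chunks" not in ds.sa.columns:
        raise ValueError("sa.chunks is required")
    chunks = np.asarray(ds.sa["chunks"])
    uniq = np.unique(chunks)
    if len(uniq) < 2:
        raise ValueError("need at least 2 unique chunks")
    idx = np.arange(ds.n_samples)
    folds: list[tuple[np.ndarray, np.ndarray]] = []

    if scheme == "nfold":
        for c in uniq:
            folds.append((idx[chunks != c], idx[chunks == c]))
    elif scheme == "oddeven":
        rank = {c: r for r, c in enumerate(uniq)}
        parity = np.array([rank[c] % 2 for c in chunks])
        folds.append((idx[parity == 0], idx[parity == 1]))
        folds.append((idx[parity == 1], idx[parity == 0]))
    elif scheme == "take_k_out":
        if not 1 <= k < len(uniq):
            raise ValueError(f"k must be in [1, {len(uniq) - 1}]")
        for combo in combinations(uniq, k):
            test_mask = np.isin(chunks, combo)
            folds.append((idx[~test_mask], idx[test_mask]))
    elif scheme == "cross_grouped":
        if group_attr is None or group_attr not in ds.sa.columns:
            raise ValueError("cross_grouped needs a valid group_attr "
                             "sample attribute")
        groups = np.asarray(ds.sa[group_attr])
        guniq = np.unique(groups)
        if len(guniq) < 2:
            raise ValueError("cross_grouped needs at least 2 group values")
        for g_train in guniq:
            for g_test in guniq:
                if g_train == g_test:
                    continue
                for c in uniq:
                    train = idx[(groups == g_train) & (chunks != c)]
                    test = idx[(groups == g_test) & (chunks == c)]
                    if len(train) and len(test):
                        folds.append((train, test))
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")
    return PartitionSet(folds=folds)


def check_partitions(partitions: PartitionSet, ds: Dataset) -> list[str]:
    """Flag double-dipping and degenerate folds; returns violation messages.

    Checks per fold: train/test sample overlap, chunks appearing on both
    sides, and target classes missing from the training set.
    """
    out: list[str] = []
    chunks = np.asarray(ds.sa["chunks"]) if "chunks" in ds.sa.columns else None
    targets = np.asarray(ds.sa["targets"]) if "targets" in ds.sa.columns else None
    all_targets = np.unique(targets) if targets is not None else None
    for f, (train, test) in enumerate(partitions):
        train = np.asarray(train)
        test = np.asarray(test)
        both = np.concatenate([train, test])
        if both.size and (both.min() < 0 or both.max() >= ds.n_samples):
            out.append(f"fold {f}: sample index out of range")
            continue
        if np.intersect1d(train, test).size:
            out.append(f"fold {f}: train and test samples overlap")
        if chunks is not None:
            shared = np.intersect1d(chunks[train], chunks[test])
            if shared.size:
                out.append(f"fold {f}: chunk(s) {shared.tolist()} appear in "
                           "both train and test")
        if targets is not None:
            missing = np.setdiff1d(all_targets, targets[train])
            if missing.size:
                out.append(f"fold {f}: target class(es) {missing.tolist()} "
                           "missing from training set")
            if len(np.unique(targets[train])) < 2:
                out.append(f"fold {f}: fewer than 2 target classes in "
                           "training set")
    return out
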