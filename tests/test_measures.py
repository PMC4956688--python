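"""MVPA measures against brute-force oracles and their output contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import mvlight as mv

# behavioral dissimilarity ratings for six animal species (worked RSA input)
BEHAVIOR_DSM = np.array([
    [0.00, 0.10, 1.05, 1.10, 1.68, 1.75],
    [0.10, 0.00, 1.04, 1.05, 1.70, 1.76],
    [1.05, 1.04, 0.00, 0.39, 1.54, 1.46],
    [1.10, 1.05, 0.39, 0.00, 1.47, 1.40],
    [1.68, 1.70, 1.54, 1.47, 0.00, 0.16],
    [1.75, 1.76, 1.46, 1.40, 0.16, 0.00],
])


def assert_measure_contract(result):
    assert result.samples.shape[1] == 1
    assert mv.validate_dataset(result) == []


class TestCrossvalidation:
    def test_perfect_accuracy_on_repeated_patterns(self):
        # identical class patterns in all 4 chunks, no noise
        ds = mv.make_toy_meeg(effect_size=100, noise_sd=1e-6, seed=0)
        res = mv.crossvalidation_measure(ds)
        assert_measure_contract(res)
        assert res.samples[0, 0] == 1.0

    def test_null_accuracy_within_binomial_ci(self, meeg_ds):
        # within-chunk label permutation -> chance-level decoding
        accs = []
        null = mv.make_toy_meeg(effect_size=0.0, seed=3)
        parts = mv.make_partitions(null, "nfold")
        for seed in range(100):
            ds = null.copy()
            ds.sa["targets"] = mv.randomize_targets(null, seed)
            accs.append(mv.crossvalidation_measure(
                ds, partitions=parts).samples[0, 0])
        n_pred = 100 * null.n_samples
        assert abs(np.mean(accs) - 1 / 3) < 2.58 * np.sqrt(
            (1 / 3) * (2 / 3) / n_pred)

    def test_predictions_output_contract(self, meeg_ds):
        res = mv.crossvalidation_measure(meeg_ds, output="predictions")
        assert res.samples.shape == (meeg_ds.n_samples, 1)
        assert set(res.samples[:, 0]).issubset({1, 2, 3})
        assert np.array_equal(np.asarray(res.sa["targets"]),
                              np.asarray(meeg_ds.sa["targets"]))

    def test_train_only_normalization_is_applied(self, meeg_ds):
        res = mv.crossvalidation_measure(meeg_ds, normalization="zscore")
        assert 0.0 <= res.samples[0, 0] <= 1.0

    def test_invalid_partitions_rejected(self, meeg_ds):
        bad = mv.PartitionSet(folds=[(np.arange(6), np.arange(5, 10))])
        with pytest.raises(ValueError, match="partitions"):
            mv.crossvalidation_measure(meeg_ds, partitions=bad)


class TestCorrelation:
    def test_positive_for_reliable_patterns(self, rng):
        base = rng.normal(size=(2, 30)) * 3
        samples = np.vstack([base + rng.normal(0, .01, base.shape),
                             base + rng.normal(0, .01, base.shape)])
        ds = mv.Dataset(samples, sa={"targets": [1, 2, 1, 2],
                                     "chunks": [1, 1, 2, 2]})
        res = mv.correlation_measure(ds)
        assert_measure_contract(res)
        assert res.samples[0, 0] > 0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            X = rng.normal(size=(12, 20))
            targets = np.tile([1, 2, 3], 4)
            chunks = np.repeat([1, 2], 6)
            ds = mv.Dataset(X, sa={"targets": targets, "chunks": chunks})
            res = mv.correlation_measure(ds).samples[0, 0]
            # independent recomputation
            total = 0.0
            for h1, h2 in ((1, 2), (2, 1)):
                m1 = np.stack([X[(chunks == h1) & (targets == t)].mean(0)
                               for t in (1, 2, 3)])
                m2 = np.stack([X[(chunks == h2) & (targets == t)].mean(0)
                               for t in (1, 2, 3)])
                C = np.corrcoef(m1, m2)[:3, 3:]
                Z = np.arctanh(C)
                W = np.full((3, 3), -1 / 6.0)
                np.fill_diagonal(W, 1 / 3.0)
                total += np.sum(W * Z)
            assert np.isclose(res, total / 2, atol=1e-12)

    def test_missing_target_in_half_raises(self, rng):
        ds = mv.Dataset(rng.normal(size=(5, 4)),
                        sa={"targets": [1, 2, 1, 1, 1],
                            "chunks": [1, 1, 2, 2, 2]})
        with pytest.raises(ValueError, match="missing"):
            mv.correlation_measure(ds)

    def test_identical_halves_clamped_with_warning(self):
        base = np.arange(12, dtype=float).reshape(2, 6)
        ds = mv.Dataset(np.vstack([base, base]),
                        sa={"targets": [1, 2, 1, 2], "chunks": [1, 1, 2, 2]})
        with pytest.warns(RuntimeWarning, match="clamp"):
            res = mv.correlation_measure(ds)
        assert np.isfinite(res.samples[0, 0])

    def test_null_mean_near_zero(self, rng):
        vals = []
        for _ in range(200):
            ds = mv.Dataset(rng.normal(size=(8, 15)),
                            sa={"targets": np.tile([1, 2], 4),
                                "chunks": np.repeat([1, 2], 4)})
            vals.append(mv.correlation_measure(ds).samples[0, 0])
        from scipy.stats import ttest_1samp
        assert ttest_1samp(vals, 0.0).pvalue > 0.001


class TestTargetDsmCorr:
    def test_identical_dsms_give_one(self, rng):
        X = rng.normal(size=(6, 40))
        neural = squareform(pdist(X, "correlation"))
        res = mv.target_dsm_corr_measure(mv.Dataset(X), target_dsm=neural)
        assert_measure_contract(res)
        assert np.isclose(res.samples[0, 0], 1.0)

    def test_behavioral_matrix_matches_oracle(self, rng):
        X = rng.normal(size=(6, 50))
        res = mv.target_dsm_corr_measure(mv.Dataset(X),
                                         target_dsm=BEHAVIOR_DSM)
        oracle = np.corrcoef(pdist(X, "correlation"),
                             squareform(BEHAVIOR_DSM, checks=False))[0, 1]
        assert np.isclose(res.samples[0, 0], oracle, atol=1e-12)

    def test_spearman_matches_scipy(self, rng):
        from scipy.stats import spearmanr
        X = rng.normal(size=(6, 50))
        res = mv.target_dsm_corr_measure(mv.Dataset(X),
                                         target_dsm=BEHAVIOR_DSM,
                                         corr_type="spearman")
        oracle = spearmanr(pdist(X, "correlation"),
                           squareform(BEHAVIOR_DSM, checks=False)).statistic
        assert np.isclose(res.samples[0, 0], oracle, atol=1e-12)

    def test_size_mismatch_and_asymmetry_rejected(self, rng):
        X = rng.normal(size=(6, 10))
        with pytest.raises(ValueError):
            mv.target_dsm_corr_measure(mv.Dataset(X),
                                       target_dsm=np.zeros((5, 5)))
        asym = BEHAVIOR_DSM.copy()
        asym[0, 1] = 9.0
        with pytest.raises(ValueError, match="symmetric"):
            mv.target_dsm_corr_measure(mv.Dataset(X), target_dsm=asym)


class TestDissimilarityMatrix:
    def test_pair_enumeration(self, rng):
        ds = mv.Dataset(rng.normal(size=(3, 8)))
        res = mv.dissimilarity_matrix_measure(ds)
        assert_measure_contract(res)
        assert list(zip(res.sa["targets1"], res.sa["targets2"])) == \
            [(1, 2), (1, 3), (2, 3)]

    def test_duplicate_rows_have_zero_distance(self, rng):
        X = rng.normal(size=(4, 8))
        X[2] = X[0]
        res = mv.dissimilarity_matrix_measure(mv.Dataset(X),
                                              metric="euclidean")
        pair = list(zip(res.sa["targets1"], res.sa["targets2"])).index((1, 3))
        assert res.samples[pair, 0] == 0.0

    def test_unflatten_gives_square_matrix(self, rng):
        X = rng.normal(size=(5, 12))
        res = mv.dissimilarity_matrix_measure(mv.Dataset(X))
        arr, labels, _ = mv.unflatten(res, axis="samples", fill=0.0)
        M = arr[:, :, 0]
        assert M.shape == (5, 5)
        full = M + M.T
        assert np.allclose(full, squareform(pdist(X, "correlation")))
        assert np.allclose(np.diag(full), 0.0)

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValueError):
            mv.dissimilarity_matrix_measure(mv.Dataset(rng.normal(size=(3, 4))),
                                            metric="nope")


def _timegen_input(effect_size=5.0, time_constant=True, seed=0,
                   n_time=5, n_chan=6):
    """chan x time data with time on the sample axis, chunks 1=train 2=test."""
    rng = np.random.default_rng(seed)
    pattern = rng.normal(size=(2, n_chan)) * effect_size
    arr = np.empty((8, n_chan, n_time))
    targets = np.tile([1, 2], 4)
    chunks = np.repeat([1, 2], 4)
    for r in range(8):
        for t in range(n_time):
            pat = pattern[targets[r] - 1] if time_constant \
                else np.roll(pattern[targets[r] - 1], t)
            arr[r, :, t] = pat + rng.normal(0, 0.5, n_chan)
    ds = mv.flatten(arr, ["chan", "time"],
                    {"chan": [f"c{i}" for i in range(n_chan)],
                     "time": 0.1 * np.arange(n_time)})
    ds.sa["targets"] = targets
    ds.sa["chunks"] = chunks
    moved = mv.dim_transpose(ds, "time", "samples")
    return moved


class TestDimGeneralization:
    def test_time_constant_patterns_generalize_everywhere(self):
        ds = _timegen_input(effect_size=20, time_constant=True)
        res = mv.dim_generalization_measure(ds, "time", radius=0)
        assert_measure_contract(res)
        assert res.samples.shape == (25, 1)
        assert np.all(res.samples == 1.0)

    def test_output_sdim_coordinates(self):
        ds = _timegen_input()
        res = mv.dim_generalization_measure(ds, "time", radius=0)
        assert res.a.sdim.labels == ["train_time", "test_time"]
        assert np.allclose(res.a.sdim.values["train_time"],
                           0.1 * np.arange(5))
        # train position varies fastest
        assert np.array_equal(np.asarray(res.sa["train_time"])[:5],
                              np.arange(1, 6))
        assert np.array_equal(np.asarray(res.sa["test_time"])[:5],
                              np.ones(5, int))

    def test_matches_brute_force_double_loop(self):
        ds = _timegen_input(effect_size=1.0, time_constant=False, seed=3)
        res = mv.dim_generalization_measure(ds, "time", radius=0)
        chunks = np.asarray(ds.sa["chunks"])
        pos = np.asarray(ds.sa["time"])
        targets = np.asarray(ds.sa["targets"])
        k = 0
        for p_test in range(1, 6):
            for p_train in range(1, 6):
                tr = (chunks == 1) & (pos == p_train)
                te = (chunks == 2) & (pos == p_test)
                pred = mv.classify_lda(ds.samples[tr], targets[tr],
                                       ds.samples[te])
                acc = np.mean(pred == targets[te])
                assert np.isclose(res.samples[k, 0], acc)
                k += 1

    def test_radius_windows_match_manual_feature_concat(self):
        ds = _timegen_input(effect_size=1.0, time_constant=False, seed=5)
        res = mv.dim_generalization_measure(ds, "time", radius=1)
        chunks = np.asarray(ds.sa["chunks"])
        pos = np.asarray(ds.sa["time"])
        targets = np.asarray(ds.sa["targets"])
        # interior pair (train=3, test=3): offsets -1, 0, +1
        def window(chunk, center):
            cols = []
            for o in (-1, 0, 1):
                rows = np.flatnonzero((chunks == chunk) &
                                      (pos == center + o))
                cols.append(ds.samples[rows])
            return np.concatenate(cols, axis=1), \
                targets[np.flatnonzero((chunks == chunk) & (pos == center))]
        Xtr, ytr = window(1, 3)
        Xte, yte = window(2, 3)
        acc = np.mean(mv.classify_lda(Xtr, ytr, Xte) == yte)
        k = (3 - 1) * 5 + (3 - 1)  # row for (train=3, test=3)
        assert np.isclose(res.samples[k, 0], acc)

    def test_bad_chunks_rejected(self):
        ds = _timegen_input()
        ds.sa["chunks"] = np.asarray(ds.sa["chunks"]) + 1
        with pytest.raises(ValueError, match="chunks"):
            mv.dim_generalization_measure(ds, "time")

    def test_dimension_on_wrong_axis_rejected(self, meeg_ds):
        with pytest.raises(ValueError, match="sample dimension"):
            mv.dim_generalization_measure(meeg_ds, "time")
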