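"""Structural operations on the uniform dataset container."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mvlight as mv
from mvlight.dataset import DatasetAttrs, DimensionList


def small_ds(n_samples=2, n_features=3):
    return mv.Dataset(np.arange(n_samples * n_features, dtype=float)
                      .reshape(n_samples, n_features),
                      sa={"targets": np.arange(1, n_samples + 1),
                          "chunks": np.ones(n_samples, dtype=int)})


class TestValidate:
    def test_well_formed_dataset_has_no_violations(self, meeg_ds):
        assert mv.validate_dataset(small_ds()) == []
        assert mv.validate_dataset(meeg_ds) == []

    def test_wrong_sa_length_named(self):
        ds = small_ds()
        ds.sa = pd.DataFrame({"targets": [1, 2, 3]})
        bad = mv.validate_dataset(ds)
        assert len(bad) == 1 and "sa.targets" in bad[0]

    def test_zero_based_dim_index_flagged(self, meeg_ds):
        # dimension index columns are 1-based; a 0 violates the contract
        meeg_ds.fa.loc[0, "chan"] = 0
        bad = mv.validate_dataset(meeg_ds)
        assert any("fa.chan" in b for b in bad)

    def test_ops_produce_valid_datasets(self, meeg_ds):
        sliced = mv.slice_dataset(meeg_ds, [3, 1], "samples")
        stacked = mv.stack([sliced, sliced], "samples")
        renamed = mv.dim_rename(meeg_ds, "time", "freq")
        moved = mv.dim_transpose(meeg_ds, "time", "samples")
        for ds in (sliced, stacked, renamed, moved):
            assert mv.validate_dataset(ds) == []


class TestSliceStack:
    def test_all_true_mask_is_identity(self, meeg_ds):
        for axis, n in (("samples", meeg_ds.n_samples),
                        ("features", meeg_ds.n_features)):
            assert mv.slice_dataset(meeg_ds, np.ones(n, bool),
                                    axis).equals(meeg_ds)

    def test_index_list_reorders_rows_and_sa(self, meeg_ds):
        out = mv.slice_dataset(meeg_ds, [3, 1], "samples")
        assert np.array_equal(out.samples, meeg_ds.samples[[3, 1]])
        assert np.array_equal(np.asarray(out.sa["targets"]),
                              np.asarray(meeg_ds.sa["targets"])[[3, 1]])

    def test_roi_mask_restricts_features(self, fmri_ds):
        mask = np.zeros(fmri_ds.n_features, bool)
        mask[[2, 5, 7]] = True
        roi = mv.slice_dataset(fmri_ds, mask, "features")
        assert roi.n_features == 3
        assert np.array_equal(roi.samples, fmri_ds.samples[:, [2, 5, 7]])
        assert np.array_equal(np.asarray(roi.fa["i"]),
                              np.asarray(fmri_ds.fa["i"])[[2, 5, 7]])

    def test_out_of_range_and_bad_mask_raise(self, meeg_ds):
        with pytest.raises(IndexError):
            mv.slice_dataset(meeg_ds, [999], "samples")
        with pytest.raises(ValueError):
            mv.slice_dataset(meeg_ds, np.ones(3, bool), "features")

    def test_stack_singleton_is_identity(self, meeg_ds):
        assert mv.stack([meeg_ds], "samples").equals(meeg_ds)

    def test_chunk_partition_roundtrip(self, meeg_ds):
        chunks = np.asarray(meeg_ds.sa["chunks"])
        parts = [mv.slice_dataset(meeg_ds, chunks == c, "samples")
                 for c in np.unique(chunks)]
        merged = mv.stack(parts, "samples")
        order = np.lexsort((np.asarray(merged.sa["targets"]),
                            np.asarray(merged.sa["chunks"])))
        expect = np.lexsort((np.asarray(meeg_ds.sa["targets"]),
                             np.asarray(meeg_ds.sa["chunks"])))
        assert np.array_equal(merged.samples[order],
                              meeg_ds.samples[expect])

    def test_stack_mismatching_fa_names_column(self, meeg_ds):
        other = meeg_ds.copy()
        other.fa["chan"] = np.asarray(other.fa["chan"])[::-1]
        with pytest.raises(ValueError, match="chan"):
            mv.stack([meeg_ds, other], "samples")

    def test_stack_empty_list_raises(self):
        with pytest.raises(ValueError):
            mv.stack([], "samples")

    def test_feature_stack_requires_matching_sa(self, meeg_ds):
        other = meeg_ds.copy()
        other.sa["targets"] = np.asarray(other.sa["targets"])[::-1]
        with pytest.raises(ValueError, match="targets"):
            mv.stack([meeg_ds, other], "features")


class TestFlattenUnflatten:
    def test_roundtrip_is_exact(self, rng):
        arr = rng.normal(size=(2, 2, 3, 2))
        values = {"a": [10, 20], "b": [1.5, 2.5, 3.5], "c": ["u", "v"]}
        ds = mv.flatten(arr, ["a", "b", "c"], values)
        assert ds.n_features == 12
        assert set(ds.a.fdim.labels) == {"a", "b", "c"}
        back, labels, vals = mv.unflatten(ds)
        assert labels == ["a", "b", "c"]
        assert np.array_equal(back, arr)

    def test_first_label_varies_fastest(self):
        arr = np.arange(6).reshape(1, 3, 2, order="F")
        ds = mv.flatten(arr, ["p", "q"], {"p": [1, 2, 3], "q": [1, 2]})
        # feature order must walk p fastest: values 0,1,2 then 3,4,5
        assert np.array_equal(ds.samples[0], np.arange(6))
        assert np.array_equal(np.asarray(ds.fa["p"]), [1, 2, 3, 1, 2, 3])
        assert np.array_equal(np.asarray(ds.fa["q"]), [1, 1, 1, 2, 2, 2])

    def test_missing_grid_position_gets_fill(self):
        ds = mv.flatten(np.arange(6, dtype=float).reshape(1, 3, 2),
                        ["p", "q"], {"p": [1, 2, 3], "q": [1, 2]})
        partial = mv.slice_dataset(ds, [0, 1, 3, 4, 5], "features")
        back, _, _ = mv.unflatten(partial, fill=-99.0)
        assert back[0, 2, 0] == -99.0
        assert back[0, 0, 0] == 0.0

    def test_duplicate_position_raises(self):
        ds = mv.flatten(np.zeros((1, 2)), ["p"], {"p": [1, 2]})
        ds.fa["p"] = [1, 1]
        with pytest.raises(ValueError, match="duplicate"):
            mv.unflatten(ds)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mv.flatten(np.zeros((1, 3)), ["p"], {"p": [1, 2]})

    @settings(deadline=None, max_examples=25)
    @given(st.integers(1, 3), st.integers(1, 4), st.integers(1, 3),
           st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_property(self, n, d1, d2, seed):
        arr = np.random.default_rng(seed).normal(size=(n, d1, d2))
        ds = mv.flatten(arr, ["u", "w"],
                        {"u": np.arange(d1), "w": np.arange(d2)})
        back, _, _ = mv.unflatten(ds)
        assert np.array_equal(back, arr)


class TestDimTranspose:
    def test_values_preserved_by_indexed_lookup(self, rng):
        arr = rng.normal(size=(2, 9, 5))
        ds = mv.flatten(arr, ["chan", "time"],
                        {"chan": np.arange(9), "time": np.arange(5)})
        ds.sa["targets"] = [1, 2]
        ds.sa["chunks"] = [1, 1]
        out = mv.dim_transpose(ds, "time", "samples")
        assert out.samples.shape == (10, 9)
        assert "time" in out.sa.columns and "time" in out.a.sdim.labels
        for r in range(out.n_samples):
            t = int(out.sa["time"][r]) - 1
            old_row = r % 2
            for c in range(out.n_features):
                ch = int(out.fa["chan"][c]) - 1
                assert out.samples[r, c] == arr[old_row, ch, t]

    def test_roundtrip_up_to_order(self, meeg_ds):
        back = mv.dim_transpose(mv.dim_transpose(meeg_ds, "time", "samples"),
                                "time", "features")
        assert back.samples.shape == meeg_ds.samples.shape
        # compare feature-by-feature via dimension coordinates
        key = lambda ds: np.lexsort((np.asarray(ds.fa["chan"]),
                                     np.asarray(ds.fa["time"])))
        row_key = lambda ds: np.lexsort((np.asarray(ds.sa["targets"]),
                                         np.asarray(ds.sa["chunks"])))
        a = meeg_ds.samples[np.ix_(row_key(meeg_ds), key(meeg_ds))]
        b = back.samples[np.ix_(row_key(back), key(back))]
        assert np.allclose(a, b)

    def test_unknown_label_raises(self, meeg_ds):
        with pytest.raises(ValueError):
            mv.dim_transpose(meeg_ds, "nope", "samples")

    def test_non_dense_raises(self, meeg_ds):
        broken = mv.slice_dataset(
            meeg_ds, np.arange(meeg_ds.n_features - 1), "features")
        with pytest.raises(ValueError, match="dense"):
            mv.dim_transpose(broken, "time", "samples")


class TestDimRename:
    def test_roundtrip_identity(self, meeg_ds):
        out = mv.dim_rename(mv.dim_rename(meeg_ds, "time", "freq"),
                            "freq", "time")
        assert out.equals(meeg_ds)

    def test_collision_and_missing_raise(self, meeg_ds):
        with pytest.raises(ValueError):
            mv.dim_rename(meeg_ds, "time", "chan")
        with pytest.raises(ValueError):
            mv.dim_rename(meeg_ds, "ghost", "new")

    def test_sdim_rename_mirrors_fdim(self, meeg_ds):
        moved = mv.dim_transpose(meeg_ds, "time", "samples")
        out = mv.dim_rename(moved, "time", "lag")
        assert "lag" in out.a.sdim.labels and "lag" in out.sa.columns
        assert np.array_equal(np.asarray(out.sa["lag"]),
                              np.asarray(moved.sa["time"]))


class TestChunkize:
    def test_round_robin_assignment(self):
        ds = mv.Dataset(np.zeros((32, 1)),
                        sa={"targets": np.ones(32, int),
                            "chunks": np.repeat([1, 2, 3, 4], 8)})
        out = mv.chunkize(ds, 2)
        chunks = np.asarray(ds.sa["chunks"])
        assert set(out[np.isin(chunks, [1, 3])]) == {1}
        assert set(out[np.isin(chunks, [2, 4])]) == {2}
        assert np.sum(out == 1) == np.sum(out == 2) == 16

    def test_nchunks_equal_unique_is_relabeling(self, meeg_ds):
        out = mv.chunkize(meeg_ds, 4)
        chunks = np.asarray(meeg_ds.sa["chunks"])
        mapping = {c: set(out[chunks == c]) for c in np.unique(chunks)}
        assert all(len(v) == 1 for v in mapping.values())
        assert sorted(np.unique(out)) == [1, 2, 3, 4]

    def test_too_few_chunks_raises(self):
        ds = mv.Dataset(np.zeros((4, 1)),
                        sa={"targets": [1, 1, 2, 2], "chunks": [1, 1, 2, 2]})
        with pytest.raises(ValueError):
            mv.chunkize(ds, 3)


class TestRandomizeTargets:
    def test_single_sample_chunks_unchanged(self):
        ds = mv.Dataset(np.zeros((3, 1)),
                        sa={"targets": [1, 2, 3], "chunks": [1, 2, 3]})
        assert np.array_equal(mv.randomize_targets(ds, 5), [1, 2, 3])

    def test_deterministic_per_seed(self, meeg_ds):
        assert np.array_equal(mv.randomize_targets(meeg_ds, 7),
                              mv.randomize_targets(meeg_ds, 7))
        outs = {tuple(mv.randomize_targets(meeg_ds, s)) for s in range(20)}
        assert len(outs) > 1

    def test_chunkwise_histograms_preserved(self, meeg_ds):
        chunks = np.asarray(meeg_ds.sa["chunks"])
        targets = np.asarray(meeg_ds.sa["targets"])
        for seed in range(100):
            perm = mv.randomize_targets(meeg_ds, seed)
            for c in np.unique(chunks):
                assert sorted(perm[chunks == c]) == \
                    sorted(targets[chunks == c])


class TestNormalize:
    def test_demean_zero_feature_means(self, meeg_ds):
        out, _ = mv.normalize(meeg_ds, "demean", "samples")
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-12

    def test_train_params_apply_to_test(self, meeg_ds):
        half = meeg_ds.n_samples // 2
        train = mv.slice_dataset(meeg_ds, np.arange(half), "samples")
        _, params = mv.normalize(train, "demean", "samples")
        test, _ = mv.normalize(train, "demean", "samples", params=params)
        assert np.abs(test.samples.mean(axis=0)).max() < 1e-12

    def test_zscore_constant_feature_nan_with_warning(self):
        ds = mv.Dataset(np.column_stack([np.arange(4.0), np.ones(4)]))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out, _ = mv.normalize(ds, "zscore", "samples")
        assert np.all(np.isnan(out.samples[:, 1]))
        assert np.all(np.isfinite(out.samples[:, 0]))

    def test_zscore_uses_sample_std(self, rng):
        X = rng.normal(size=(6, 3))
        out, params = mv.normalize(mv.Dataset(X), "zscore", "samples")
        expect = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(out.samples, expect)
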