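"""Tests for the block-structured data model and preprocessing."""

import hashlib

import numpy as np
import pytest

from voxencode.data import (
    DataFormatError,
    EncodingDataset,
    FeatureBlock,
    ResponseBlock,
    average_repeats,
    export_tsv,
    load_dataset,
    preprocess,
    save_dataset,
    split_validation,
)
from voxencode.synthetic import SyntheticConfig, generate_dataset

from conftest import make_dataset


def _checksum(dataset):
    h = hashlib.sha256()
    for fb in dataset.features:
        h.update(fb.values.tobytes())
    for rb in dataset.responses:
        h.update(rb.values.tobytes())
        if rb.repeats is not None:
            h.update(rb.repeats.tobytes())
    return h.hexdigest()


class TestValidation:
    def test_repeat_mean_mismatch_rejected(self, rng):
        reps = rng.standard_normal((3, 10, 2))
        with pytest.raises(ValueError, match="repeat mean"):
            ResponseBlock(values=reps.mean(0) + 0.1, block_id="b", repeats=reps)

    def test_single_repeat_rejected(self, rng):
        reps = rng.standard_normal((1, 10, 2))
        with pytest.raises(ValueError, match="R >= 2"):
            ResponseBlock(values=reps.mean(0), block_id="b", repeats=reps)

    def test_unpaired_block_rejected(self, rng):
        fb = FeatureBlock(rng.standard_normal((5, 2)), "a", "train")
        rb = ResponseBlock(rng.standard_normal((5, 2)), "other")
        with pytest.raises(DataFormatError):
            EncodingDataset([fb], [rb], ["g", "g"])


class TestPreprocess:
    def test_discard_drops_first_samples(self, rng):
        """A 600 s block loses its first 6 s, leaving 594 samples."""
        ds = make_dataset(rng, T_train=600, n_train=1, n_test=0)
        out = preprocess(ds, discard_seconds=6)
        assert out.features[0].n_samples == 594
        np.testing.assert_array_equal(out.features[0].values, ds.features[0].values[6:])

    def test_zscore_moments_and_idempotence(self, rng):
        ds = make_dataset(rng)
        once = preprocess(ds, discard_seconds=4)
        for rb in once.responses:
            np.testing.assert_allclose(rb.values.mean(axis=0), 0, atol=1e-8)
            np.testing.assert_allclose(rb.values.std(axis=0), 1, atol=1e-8)
        twice = preprocess(once, discard_seconds=0)
        for a, b in zip(once.responses, twice.responses):
            np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_constant_channel_zeroed_with_warning(self, rng):
        ds = make_dataset(rng, n_train=1, n_test=0)
        values = ds.responses[0].values.copy()
        values[:, 0] = 3.14
        ds = EncodingDataset(
            ds.features, [ResponseBlock(values, ds.responses[0].block_id)], ds.voxel_groups
        )
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess(ds, discard_seconds=2)
        assert np.all(out.responses[0].values[:, 0] == 0)

    def test_block_shorter_than_discard_rejected(self, rng):
        ds = make_dataset(rng, T_train=5, T_test=5)
        with pytest.raises(ValueError, match="discard"):
            preprocess(ds, discard_seconds=6)

    def test_repeats_stay_consistent_after_zscore(self, rng):
        ds = make_dataset(rng, n_repeats=4)
        out = preprocess(ds, discard_seconds=3)
        for rb in out.responses:
            if rb.repeats is not None:
                np.testing.assert_allclose(rb.values, rb.repeats.mean(axis=0), atol=1e-10)

    def test_input_not_mutated(self, rng):
        ds = make_dataset(rng, n_repeats=3)
        before = _checksum(ds)
        preprocess(ds, discard_seconds=5)
        split_validation(ds, tail_seconds=10)
        assert _checksum(ds) == before


class TestSplitValidation:
    def test_tail_lengths(self, rng):
        """594-sample training blocks split into 549 train + 45 validation."""
        ds = make_dataset(rng, T_train=594, n_train=2, n_test=1)
        train, val = split_validation(ds, tail_seconds=45)
        for fb in train.features:
            if fb.role == "train":
                assert fb.n_samples == 549
        for fb in val.features:
            assert fb.n_samples == 45

    def test_zero_tail_leaves_train_unchanged(self, rng):
        ds = make_dataset(rng)
        train, val = split_validation(ds, tail_seconds=0)
        assert val is None
        np.testing.assert_array_equal(train.features[0].values, ds.features[0].values)

    def test_reassembly_restores_originals(self, rng):
        ds = make_dataset(rng)
        train, val = split_validation(ds, tail_seconds=17)
        vmap = {fb.block_id: fb for fb in val.features}
        for fb in train.features:
            if fb.role != "train":
                continue
            rebuilt = np.concatenate([fb.values, vmap[fb.block_id].values])
            orig = next(b for b in ds.features if b.block_id == fb.block_id)
            np.testing.assert_array_equal(rebuilt, orig.values)

    def test_tail_too_long_rejected(self, rng):
        ds = make_dataset(rng, T_train=40)
        with pytest.raises(ValueError, match="tail"):
            split_validation(ds, tail_seconds=40)

    def test_preprocess_then_split_commutes(self, rng):
        ds = make_dataset(rng)
        a_train, a_val = split_validation(preprocess(ds, 6), 20)
        # one pass: discard then split manually on raw arrays
        pre = preprocess(ds, 6)
        b_train, b_val = split_validation(pre, 20)
        for x, y in zip(a_train.responses, b_train.responses):
            np.testing.assert_array_equal(x.values, y.values)
        for x, y in zip(a_val.responses, b_val.responses):
            np.testing.assert_array_equal(x.values, y.values)


class TestAverageRepeats:
    def test_identical_repeats_have_zero_sem(self, rng):
        base = rng.standard_normal((10, 3))
        reps = np.stack([base] * 5)
        block = ResponseBlock(base, "b", repeats=reps)
        mean, sem = average_repeats(block)
        np.testing.assert_allclose(mean, base, atol=1e-12)
        np.testing.assert_allclose(sem, 0, atol=1e-15)

    def test_two_point_formula(self):
        reps = np.zeros((2, 1, 1))
        reps[0, 0, 0], reps[1, 0, 0] = 1.0, 3.0
        block = ResponseBlock(reps.mean(0), "b", repeats=reps)
        mean, sem = average_repeats(block)
        assert mean[0, 0] == 2.0
        assert sem[0, 0] == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        reps = rng.standard_normal((10, 7, 4))
        block = ResponseBlock(reps.mean(0), "b", repeats=reps)
        mean, sem = average_repeats(block)
        for t in range(7):
            for v in range(4):
                x = reps[:, t, v]
                assert mean[t, v] == pytest.approx(x.mean(), abs=1e-12)
                assert sem[t, v] == pytest.approx(
                    x.std(ddof=1) / np.sqrt(10), abs=1e-12
                )

    def test_no_repeats_rejected(self, rng):
        block = ResponseBlock(rng.standard_normal((5, 2)), "b")
        with pytest.raises(ValueError, match="repeats"):
            average_repeats(block)


class TestSerialization:
    def test_hdf5_roundtrip_bit_exact(self, rng, tmp_path):
        ds = make_dataset(rng, n_repeats=3, groups=["a", "a", "b", "b"])
        path = tmp_path / "ds.h5"
        save_dataset(ds, path)
        back = load_dataset(path)
        assert back.voxel_groups == ds.voxel_groups
        assert back.sampling_interval == ds.sampling_interval
        fmap = {b.block_id: b for b in back.features}
        for fb in ds.features:
            np.testing.assert_array_equal(fmap[fb.block_id].values, fb.values)
            assert fmap[fb.block_id].role == fb.role
        rmap = {b.block_id: b for b in back.responses}
        for rb in ds.responses:
            np.testing.assert_array_equal(rmap[rb.block_id].values, rb.values)
            if rb.repeats is not None:
                np.testing.assert_array_equal(rmap[rb.block_id].repeats, rb.repeats)

    def test_synthetic_dataset_roundtrips_with_repeats(self, tmp_path):
        cfg = SyntheticConfig(
            n_train_blocks=2, n_test_blocks=1, scale=0.1, n_voxels=3,
            validation_tail_seconds=20,
        )
        ds, _ = generate_dataset(cfg, seed=5)
        save_dataset(ds, tmp_path / "s.h5")
        back = load_dataset(tmp_path / "s.h5")
        assert any(rb.repeats is not None for rb in back.responses)

    def test_missing_response_dataset_is_parse_error(self, rng, tmp_path):
        import h5py

        ds = make_dataset(rng)
        path = tmp_path / "bad.h5"
        save_dataset(ds, path)
        with h5py.File(path, "a") as f:
            del f["blocks/tr0/responses"]
        with pytest.raises(DataFormatError, match="tr0"):
            load_dataset(path)

    def test_tsv_export_writes_all_blocks(self, rng, tmp_path):
        ds = make_dataset(rng, n_train=1, n_test=1)
        export_tsv(ds, tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {"tr0.features.tsv", "te0.responses.tsv", "voxel_groups.tsv"} <= names
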