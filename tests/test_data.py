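import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treefuse as tf
from treefuse.data import _largest_remainder


def _write_dataset(tmp_path, sample_sets):
    """Three tiny matrices with (possibly different) sample rows."""
    paths = []
    for i, samples in enumerate(sample_sets, 1):
        df = pd.DataFrame(
            np.arange(len(samples) * 3, dtype=float).reshape(len(samples), 3),
            index=samples, columns=[f"g{i}_{j}" for j in range(3)],
        )
        p = tmp_path / f"mod{i}.tsv"
        df.to_csv(p, sep="\t", index_label="sample_id")
        paths.append(str(p))
    all_samples = sorted(set().union(*sample_sets))
    lab = pd.DataFrame({"label": ["A" if s < "s3" else "B" for s in all_samples]},
                       index=all_samples)
    label_path = tmp_path / "labels.tsv"
    lab.to_csv(label_path, sep="\t", index_label="sample_id")
    return paths, str(label_path)


class TestReadOmics:
    def test_complete_case_alignment(self, tmp_path):
        # sample s2 missing from modality 2 -> dropped everywhere
        full = ["s0", "s1", "s2", "s3", "s4"]
        paths, labels = _write_dataset(
            tmp_path, [full, ["s0", "s1", "s3", "s4"], full])
        ds = tf.read_omics(paths, labels)
        assert ds.n_samples == 4
        assert "s2" not in ds.sample_ids
        assert all(m.shape == (4, 3) for m in ds.matrices)

    def test_empty_intersection_errors(self, tmp_path):
        paths, labels = _write_dataset(
            tmp_path, [["s0", "s1"], ["s2", "s3"], ["s0", "s1"]])
        with pytest.raises(ValueError, match="no samples"):
            tf.read_omics(paths, labels)

    def test_round_trip(self, tmp_path, small_sim):
        dataset, _ = small_sim
        paths, label_path = tf.write_omics(dataset, str(tmp_path))
        back = tf.read_omics(paths, label_path)
        assert back.sample_ids == dataset.sample_ids
        assert back.feature_names == dataset.feature_names
        np.testing.assert_array_equal(back.labels, dataset.labels)
        for a, b in zip(back.matrices, dataset.matrices):
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_rows_follow_sample_ids(self, tmp_path):
        full = ["s0", "s1", "s3"]
        paths, labels = _write_dataset(tmp_path, [full] * 3)
        ds = tf.read_omics(paths, labels)
        for m in ds.matrices:
            assert m.shape[0] == len(ds.sample_ids)


class TestDatasetInvariants:
    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="every class"):
            tf.OmicsDataset(
                matrices=[np.zeros((4, 2))] * 3,
                labels=[0, 0, 1, 1], class_count=3,
                feature_names=[["a", "b"]] * 3,
                sample_ids=[f"s{i}" for i in range(4)],
            )

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tf.OmicsDataset(
                matrices=[np.zeros((4, 2)), np.zeros((3, 2)), np.zeros((4, 2))],
                labels=[0, 1, 0, 1], class_count=2,
                feature_names=[["a", "b"]] * 3,
                sample_ids=[f"s{i}" for i in range(4)],
            )


class TestSplits:
    def test_exact_proportional_counts(self):
        labels = np.repeat([0, 1, 2], [60, 30, 10])
        spec = tf.make_splits(labels, [0])[0]
        assert (spec.train.size, spec.val.size, spec.test.size) == (60, 20, 20)
        counts = np.bincount(labels[spec.train], minlength=3)
        np.testing.assert_array_equal(counts, [36, 18, 6])

    def test_same_seed_identical(self):
        labels = np.repeat([0, 1], [50, 50])
        a, b = tf.make_splits(labels, [7])[0], tf.make_splits(labels, [7])[0]
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_different_seeds_differ(self):
        labels = np.repeat([0, 1], [50, 50])
        a, b = tf.make_splits(labels, [0, 1])
        assert not (np.array_equal(a.train, b.train)
                    and np.array_equal(a.val, b.val))

    def test_small_class_rejected(self):
        labels = np.array([0] * 50 + [1] * 2)
        with pytest.raises(ValueError, match="fewer than"):
            tf.make_splits(labels, [0])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(0, 2), min_size=30, max_size=120).filter(
        lambda ls: min(np.bincount(ls, minlength=3)) >= 5))
    def test_stratification_property(self, ls):
        labels = np.array(ls)
        spec = tf.make_splits(labels, [11])[0]
        n = labels.size
        union = np.sort(np.concatenate([spec.train, spec.val, spec.test]))
        np.testing.assert_array_equal(union, np.arange(n))
        for c in range(3):
            n_c = (labels == c).sum()
            in_train = (labels[spec.train] == c).sum()
            assert abs(in_train / spec.train.size - n_c / n) \
                <= 1.0 / spec.train.size + 1e-12


def test_largest_remainder_sums():
    for n in (10, 37, 100, 431):
        counts = _largest_remainder(n, (0.6, 0.2, 0.2))
        assert sum(counts) == n


class TestRunConfig:
    def test_defaults_are_selected_operating_point(self):
        cfg = tf.RunConfig()
        assert (cfg.tree_count, cfg.hidden_width, cfg.batch_size) == (100, 64, 64)
        assert (cfg.learning_rate, cfg.dropout_rate, cfg.l2_lambda) == (0.0001, 0.5, 0.01)
        assert (cfg.max_epochs, cfg.patience, cfg.min_delta) == (1000, 10, 0.001)
        assert (cfg.cp_rank, cfg.residual_block_count) == (48, 3)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            tf.RunConfig(dropout_rate=1.5)
        with pytest.raises(ValueError):
            tf.RunConfig(cp_rank=0)
        with pytest.raises(ValueError):
            tf.RunConfig(fusion="bilinear")

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("cp_rank: 8\nlearning_rate: 0.001\n")
        cfg = tf.load_config(str(p), max_epochs=5)
        assert cfg.cp_rank == 8
        assert cfg.learning_rate == 0.001
        assert cfg.max_epochs == 5
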