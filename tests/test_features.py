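"""Tests for the wrapper feature-selection front-end."""

import numpy as np
import pytest

from mhgs import (DescriptorDataset, FeatureMask, FSFitnessParams, HGSParams,
                  RandomStream, SVMClassifier, binarize_position,
                  run_feature_selection, split_dataset, wrapper_fitness)
from mhgs.features import Split
from mhgs.synth import SyntheticSpec, generate_dataset


@pytest.fixture(scope="module")
def small_data():
    return generate_dataset(SyntheticSpec(n_samples=80, n_features=10,
                                          n_informative=3, class_sep=3.0,
                                          flip_y=0.0, seed=5))


class TestBinarize:
    def test_all_above_threshold(self):
        mask = binarize_position([0.9, 0.5, 0.7])
        assert mask.selected.all()

    def test_mixed_coordinates(self):
        mask = binarize_position([0.7, 0.2, 0.51])
        np.testing.assert_array_equal(mask.selected, [True, False, True])

    def test_empty_falls_back_to_argmax(self):
        mask = binarize_position([0.1, 0.45, 0.2])
        np.testing.assert_array_equal(mask.selected, [False, True, False])

    def test_mask_never_empty_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mask = binarize_position(rng.random(20) * 0.49)
            assert mask.n_selected >= 1


class _FixedErrorClassifier:
    """Stub classifier reporting a preset error rate."""

    def __init__(self, error):
        self.error = error

    def clone(self):
        return self

    def fit(self, X, y):
        self._labels = np.unique(y)
        return self

    def predict(self, X):
        return np.repeat(self._labels[0], len(X))

    def error_rate(self, X, y):
        return self.error


class TestWrapperFitness:
    def make_split(self, data):
        return split_dataset(data, RandomStream(0))

    def test_zero_error_full_mask(self, small_data):
        split = self.make_split(small_data)
        mask = FeatureMask(np.ones(10, dtype=bool))
        fobj = wrapper_fitness(mask, small_data, _FixedErrorClassifier(0.0),
                               FSFitnessParams(), split)
        assert fobj == pytest.approx(0.01, abs=1e-12)

    def test_zero_error_singleton_of_hundred(self):
        data = generate_dataset(SyntheticSpec(n_samples=40, n_features=100,
                                              n_informative=5, seed=1))
        split = split_dataset(data, RandomStream(0))
        mask = FeatureMask(np.eye(100, dtype=bool)[0])
        fobj = wrapper_fitness(mask, data, _FixedErrorClassifier(0.0),
                               FSFitnessParams(), split)
        assert fobj == pytest.approx(0.0001, abs=1e-12)

    def test_total_error_lower_bound(self, small_data):
        split = self.make_split(small_data)
        mask = FeatureMask(np.ones(10, dtype=bool))
        fobj = wrapper_fitness(mask, small_data, _FixedErrorClassifier(1.0),
                               FSFitnessParams(), split)
        assert fobj >= 0.99

    def test_monotone_in_error_and_size(self, small_data):
        split = self.make_split(small_data)
        params = FSFitnessParams()
        small = FeatureMask(np.eye(10, dtype=bool)[0])
        large = FeatureMask(np.ones(10, dtype=bool))
        f_small = wrapper_fitness(small, small_data,
                                  _FixedErrorClassifier(0.2), params, split)
        f_large = wrapper_fitness(large, small_data,
                                  _FixedErrorClassifier(0.2), params, split)
        f_worse = wrapper_fitness(small, small_data,
                                  _FixedErrorClassifier(0.3), params, split)
        assert f_small < f_large
        assert f_small < f_worse

    def test_literal_mode_flags_threshold(self, small_data):
        split = self.make_split(small_data)
        mask = FeatureMask(np.ones(10, dtype=bool))
        params = FSFitnessParams(mode="literal", T=0.5)
        fobj, exceeds = wrapper_fitness(mask, small_data,
                                        _FixedErrorClassifier(0.1), params,
                                        split)
        assert fobj == pytest.approx(0.99 + 0.99 * 0.1 / 10, abs=1e-12)
        assert exceeds


class TestSplit:
    def test_balanced_hundred(self):
        data = generate_dataset(SyntheticSpec(n_samples=100, n_features=5,
                                              n_informative=2, flip_y=0.0,
                                              seed=2))
        split = split_dataset(data, RandomStream(1))
        assert len(split.test_idx) == 10
        assert len(split.train_idx) == 90
        test_labels = data.y[split.test_idx]
        counts = np.bincount(test_labels)
        assert counts.tolist() == [5, 5]

    def test_mao_sized_rounding(self):
        # 68 compounds -> round-half-up(6.8) = 7 test samples
        data = generate_dataset(SyntheticSpec(n_samples=68, n_features=20,
                                              n_informative=4, seed=3))
        split = split_dataset(data, RandomStream(1))
        assert len(split.test_idx) == 7

    def test_seed_determinism(self):
        data = generate_dataset(SyntheticSpec(n_samples=60, n_features=8,
                                              n_informative=2, seed=4))
        a = split_dataset(data, RandomStream(9))
        b = split_dataset(data, RandomStream(9))
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(11, 4))
        y = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            DescriptorDataset(X, y, [f"f{i}" for i in range(4)])


class TestRunFeatureSelection:
    def test_report_contract(self, small_data):
        report = run_feature_selection(
            small_data, HGSParams(n_agents=6, max_fe=120), runs=2,
            seeds=[1, 2])
        assert len(report["runs"]) == 2
        for entry in report["runs"]:
            assert entry["n_selected"] >= 1
            assert 0.0 <= entry["accuracy"] <= 1.0
        assert report["selection_frequency"].shape == (10,)

    def test_column_permutation_equivariance_of_scoring(self, small_data):
        """A mask's fitness depends on the selected set, not column order.

        Standardization on the training fold makes the classifier invariant
        to feature order and scale, so scoring a permuted mask on the
        column-permuted table must give the identical fitness.
        """
        perm = np.random.default_rng(3).permutation(small_data.n_features)
        permuted = DescriptorDataset(
            small_data.X[:, perm], small_data.y,
            [small_data.feature_names[j] for j in perm])
        split = split_dataset(small_data, RandomStream(4))
        params = FSFitnessParams()
        clf = SVMClassifier()
        rng = np.random.default_rng(5)
        for _ in range(5):
            sel = rng.random(small_data.n_features) < 0.4
            if not sel.any():
                sel[0] = True
            f_base = wrapper_fitness(FeatureMask(sel), small_data, clf,
                                     params, split)
            f_perm = wrapper_fitness(FeatureMask(sel[perm]), permuted, clf,
                                     params, split)
            assert f_perm == pytest.approx(f_base, abs=1e-12)

    def test_seed_count_mismatch_rejected(self, small_data):
        with pytest.raises(ValueError, match="one seed per run"):
            run_feature_selection(small_data, HGSParams(n_agents=6,
                                                        max_fe=120),
                                  runs=3, seeds=[1])


class TestCSVRoundtrip:
    def test_to_from_csv(self, tmp_path, small_data):
        path = tmp_path / "data.csv"
        small_data.to_csv(path, label_col="activity")
        loaded = DescriptorDataset.from_csv(path, label_col="activity")
        np.testing.assert_allclose(loaded.X, small_data.X)
        np.testing.assert_array_equal(loaded.y, small_data.y)
        assert loaded.feature_names == small_data.feature_names

    def test_label_col_defaults_to_last(self, tmp_path, small_data):
        path = tmp_path / "data.csv"
        small_data.to_csv(path)
        loaded = DescriptorDataset.from_csv(path)
        assert loaded.n_features == small_data.n_features
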