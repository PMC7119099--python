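"""Voxel features, random-forest classification, Gaussian cleanup, bounds."""

import numpy as np
import pytest

from handquant.core import (
    AnalysisBounds,
    BinaryMask,
    ConfigError,
    DataError,
    InsufficientDataError,
    VolumeImage,
    dice_coefficient,
)
from handquant.muscle import (
    FeatureConfig,
    MuscleClassifier,
    classify_muscle,
    extract_voxel_features,
    gaussian_cleanup,
    restrict_to_bounds,
    train_classifier,
)
from handquant.preprocess import correct_bias_field, extract_hand_mask


@pytest.fixture()
def small_image_and_mask():
    rng = np.random.default_rng(0)
    img = VolumeImage(rng.normal(100, 5, (6, 12, 12)).astype(np.float32))
    mask_data = np.zeros((6, 12, 12), dtype=bool)
    mask_data[1:5, 2:10, 2:10] = True
    return img, BinaryMask.like(img, mask_data)


class TestFeatures:
    def test_row_count_equals_hand_voxel_count(self, small_image_and_mask):
        img, mask = small_image_and_mask
        X, names = extract_voxel_features(img, mask)
        assert X.shape == (mask.count(), len(names))
        assert np.all(np.isfinite(X))

    def test_constant_image_has_zero_sd_and_gradient(self, small_image_and_mask):
        _, mask = small_image_and_mask
        img = VolumeImage(np.full((6, 12, 12), 42.0))
        X, names = extract_voxel_features(img, mask)
        for i, name in enumerate(names):
            if name.startswith("sd_") or name == "grad_mag":
                np.testing.assert_allclose(X[:, i], 0.0, atol=1e-9)

    def test_local_mean_matches_brute_force_average(self):
        rng = np.random.default_rng(1)
        data = rng.random((5, 5, 5))
        img = VolumeImage(data)
        mask_data = np.zeros((5, 5, 5), dtype=bool)
        mask_data[2, 2, 2] = True
        mask = BinaryMask.like(img, mask_data)
        cfg = FeatureConfig(
            mean_sd_radii=(1,),
            include_gradient=False,
            include_slice_position=False,
            include_boundary_distance=False,
        )
        X, names = extract_voxel_features(img, mask, cfg)
        expected = data[1:4, 1:4, 1:4].mean()
        assert X[0, names.index("mean_r1")] == pytest.approx(expected, rel=1e-12)

    def test_empty_hand_mask_rejected(self):
        img = VolumeImage(np.zeros((4, 4, 4)))
        mask = BinaryMask.like(img, np.zeros((4, 4, 4)))
        with pytest.raises(DataError):
            extract_voxel_features(img, mask)


def _separable_training_set(rng, n=2000):
    """Two intensity clusters that are trivially separable."""
    X0 = rng.normal(50, 3, (n // 2, 2))
    X1 = rng.normal(100, 3, (n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestClassifier:
    def test_separable_clusters_high_heldout_accuracy(self):
        rng = np.random.default_rng(2)
        X, y = _separable_training_set(rng)
        clf = train_classifier(X[::2], y[::2], ("a", "b"), n_trees=50, seed=1)
        acc = (clf.model.predict(X[1::2]) == y[1::2]).mean()
        assert acc >= 0.99

    def test_same_seed_gives_identical_predictions(self):
        rng = np.random.default_rng(3)
        X, y = _separable_training_set(rng)
        probe = rng.normal(75, 20, (500, 2))
        a = train_classifier(X, y, ("a", "b"), n_trees=30, seed=7).model.predict(probe)
        b = train_classifier(X, y, ("a", "b"), n_trees=30, seed=7).model.predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.random((100, 2))
        with pytest.raises(DataError):
            train_classifier(X, np.ones(100), ("a", "b"))

    def test_fingerprint_mismatch_refused(self, default_phantom, trained_classifier):
        t1, _, _, _ = default_phantom
        corrected, _ = correct_bias_field(t1)
        hand = extract_hand_mask(corrected)
        other_cfg = FeatureConfig(mean_sd_radii=(1,))
        with pytest.raises(ConfigError):
            classify_muscle(corrected, hand, trained_classifier, other_cfg)

    def test_save_load_round_trip_and_refusal(self, tmp_path, trained_classifier):
        path = tmp_path / "clf.joblib"
        trained_classifier.save(path)
        back = MuscleClassifier.load(path)
        assert back.feature_names == trained_classifier.feature_names
        import joblib

        joblib.dump({"something": "else"}, tmp_path / "junk.joblib")
        with pytest.raises(ConfigError):
            MuscleClassifier.load(tmp_path / "junk.joblib")

    def test_muscle_mask_contained_in_hand_and_deterministic(
        self, default_phantom, trained_classifier, run_config
    ):
        t1, _, _, _ = default_phantom
        corrected, _ = correct_bias_field(t1)
        hand = extract_hand_mask(corrected)
        m1 = classify_muscle(corrected, hand, trained_classifier, run_config.features)
        m2 = classify_muscle(corrected, hand, trained_classifier, run_config.features)
        assert m1.is_subset_of(hand)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_unseen_phantom_dice(self, default_phantom, trained_classifier, run_config):
        t1, _, _, truth = default_phantom
        corrected, _ = correct_bias_field(t1)
        hand = extract_hand_mask(corrected)
        muscle = classify_muscle(corrected, hand, trained_classifier, run_config.features)
        assert dice_coefficient(muscle, truth.muscle_mask()) >= 0.85


def _voi_image(values, shape=None):
    n = len(values)
    side = int(np.ceil(n ** (1 / 3)))
    shape = shape or (side, side, side)
    data = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    flat_idx = np.arange(n)
    data.flat[flat_idx] = values
    mask.flat[flat_idx] = True
    img = VolumeImage(data)
    return img, BinaryMask.like(img, mask)


class TestGaussianCleanup:
    def test_pure_gaussian_retention_matches_direct_count(self):
        rng = np.random.default_rng(5)
        values = rng.normal(100, 10, 100_000)
        img, mask = _voi_image(values)
        cleaned, report = gaussian_cleanup(img, mask)
        lo, hi = report.mean - 2 * report.sd, report.mean + 2 * report.sd
        oracle = np.mean((values >= lo) & (values <= hi))
        assert abs(report.retained_fraction - oracle) < 0.005
        assert cleaned.count() == mask.count() - report.removed_count

    def test_contaminants_removed_muscle_kept(self):
        rng = np.random.default_rng(6)
        n_muscle, n_vessel = 19_000, 1_000
        muscle_vals = rng.normal(100, 10, n_muscle)
        vessel_vals = rng.normal(160, 3, n_vessel)  # ~ mean + 6 SD
        values = np.concatenate([muscle_vals, vessel_vals])
        img, mask = _voi_image(values)
        cleaned, report = gaussian_cleanup(img, mask)
        kept = cleaned.as_bool().flat[np.arange(len(values))]
        vessel_removed = 1.0 - kept[n_muscle:].mean()
        muscle_removed = 1.0 - kept[:n_muscle].mean()
        assert vessel_removed >= 0.95
        assert muscle_removed <= 0.06

    def test_constant_voi_degenerate_flagged(self):
        img, mask = _voi_image(np.full(500, 77.0))
        cleaned, report = gaussian_cleanup(img, mask)
        assert report.degenerate
        assert cleaned.count() == mask.count()

    def test_too_few_voxels_rejected(self):
        img, mask = _voi_image(np.random.default_rng(7).normal(0, 1, 20))
        with pytest.raises(InsufficientDataError):
            gaussian_cleanup(img, mask)

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(8)
        img, mask = _voi_image(rng.normal(50, 5, 5000))
        cleaned, _ = gaussian_cleanup(img, mask)
        assert cleaned.is_subset_of(mask)


class TestRestrictToBounds:
    def _mask(self):
        rng = np.random.default_rng(9)
        data = rng.random((8, 6, 6)) > 0.5
        return BinaryMask(data)

    def test_full_bounds_is_identity(self):
        mask = self._mask()
        out = restrict_to_bounds(mask, AnalysisBounds(0, 7))
        np.testing.assert_array_equal(out.data, mask.data)

    def test_single_slice_count(self):
        mask = self._mask()
        out = restrict_to_bounds(mask, AnalysisBounds(3, 3))
        assert out.count() == int(mask.data[3].sum())
        assert out.data[[0, 1, 2, 4, 5, 6, 7]].sum() == 0

    def test_out_of_range_bounds_rejected(self):
        with pytest.raises(IndexError):
            restrict_to_bounds(self._mask(), AnalysisBounds(2, 12))
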