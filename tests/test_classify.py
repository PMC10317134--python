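"""Classifiers, crops and the split protocol (scaled geometry throughout)."""

import numpy as np
import pytest

import diffscan as dsn
from diffscan.classify import (
    CNNConfig,
    FCNNConfig,
    SplitSpec,
    SVMConfig,
    crop_central,
    load_classifier,
    predict_map,
    split_datasets,
    train_cnn,
    train_fcnn,
    train_svm,
)
from diffscan.geometry import d_spacing_to_radius


@pytest.fixture(scope="module")
def ria_training_data(small_scan, small_features):
    return small_features.profiles, small_scan.labels.ravel()


class TestSplit:
    def _datasets(self, n=4, frames=100, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"scan{i}": (rng.normal(size=(frames, 10)), rng.integers(0, 4, frames))
            for i in range(n)
        }

    def test_heldout_pool_size(self):
        ds = self._datasets(n=4, frames=1600)
        spec = SplitSpec(test_ids=("scan2", "scan3"), seed=0)
        (X_tr, y_tr), (X_val, y_val), test = split_datasets(ds, spec)
        assert sum(len(v[1]) for v in test.values()) == 3200
        assert len(X_tr) + len(X_val) == 3200
        assert len(X_val) == pytest.approx(320, abs=4)  # 10% of the pool

    def test_stratified_fractions(self):
        ds = self._datasets(n=2, frames=1000)
        (X_tr, y_tr), (X_val, y_val), _ = split_datasets(ds, SplitSpec(seed=1))
        for c in range(4):
            frac_tr = (y_tr == c).mean()
            frac_val = (y_val == c).mean()
            assert frac_tr == pytest.approx(frac_val, abs=0.02)

    def test_train_fraction_one_empty_validation(self):
        ds = self._datasets(n=2)
        (_, y_tr), (_, y_val), _ = split_datasets(ds, SplitSpec(train_fraction=1.0))
        assert len(y_val) == 0 and len(y_tr) == 200

    def test_seed_reproducibility(self):
        ds = self._datasets(n=3)
        r1 = split_datasets(ds, SplitSpec(seed=7))
        r2 = split_datasets(ds, SplitSpec(seed=7))
        np.testing.assert_array_equal(r1[0][0], r2[0][0])
        np.testing.assert_array_equal(r1[1][1], r2[1][1])


class TestCropCentral:
    def test_default_size_before_downsampling(self):
        cf = dsn.center_frame(np.ones((512, 512)), (255.5, 255.5))
        crop = crop_central(cf, radius=150, downsample=1, log_transform=False, circular=False)
        assert crop.shape == (301, 301)

    def test_all_zero_frame(self):
        cf = dsn.center_frame(np.zeros((128, 128)), (63.5, 63.5))
        assert not crop_central(cf, radius=37).any()

    def test_ring_inside_crop_high_angle_outside(self, full_geom):
        # the water ring (3.7 A ~ 111 px) falls inside a 150 px crop; the
        # 2.0 A carbon ring (~205 px) falls outside
        assert d_spacing_to_radius(3.7, full_geom) < 150
        assert d_spacing_to_radius(2.0, full_geom) > 150
        n = 512
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - 255.5, yy - 255.5)
        img = (np.abs(r - d_spacing_to_radius(3.7, full_geom)) < 2) * 50.0
        img += (np.abs(r - d_spacing_to_radius(2.0, full_geom)) < 2) * 50.0
        cf = dsn.center_frame(img, (255.5, 255.5))
        crop = crop_central(cf, radius=150, downsample=1, log_transform=False)
        assert crop.max() > 0  # water ring present
        # remove the water ring: nothing else from the 2.0 A ring leaks in
        img2 = (np.abs(r - d_spacing_to_radius(2.0, full_geom)) < 2) * 50.0
        cf2 = dsn.center_frame(img2, (255.5, 255.5))
        assert crop_central(cf2, radius=150, downsample=1, log_transform=False).max() == 0

    def test_downsample_block_mean(self):
        cf = dsn.center_frame(np.full((128, 128), 4.0), (63.5, 63.5))
        crop = crop_central(cf, radius=30, downsample=3, log_transform=False, circular=False)
        assert crop.shape == (20, 20)
        # interior blocks fully inside the frame average to exactly 4
        assert crop[10, 10] == pytest.approx(4.0)

    def test_radius_exceeding_canvas(self):
        cf = dsn.center_frame(np.ones((128, 128)), (63.5, 63.5))
        with pytest.raises(ValueError):
            crop_central(cf, radius=200)


class TestRIAClassifiers:
    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 20))
        y = np.zeros(50, dtype=int)
        with pytest.raises(ValueError, match="missing"):
            train_fcnn(X, y, FCNNConfig(seed=0))
        with pytest.raises(ValueError, match="missing"):
            train_svm(X, y, SVMConfig(seed=0))

    def test_majority_structure(self, small_geom, small_models):
        # a training set that is nearly all carbon still classifies a clean
        # carbon profile as carbon
        from diffscan.pipeline import extract_features

        scene = dsn.SceneSpec(grid_shape=(8, 8), regions=[
            (dsn.ClassLabel.amorphous_ice, [(0.8, 0.8), (2.2, 0.8), (2.2, 2.2), (0.8, 2.2)]),
        ], mixed_band=1)
        ds = dsn.simulate_scan(scene, small_models, small_geom,
                               dsn.ScanGeometry(grid_shape=(8, 8)), seed=3)
        ff = extract_features(ds, crop_radius=None)
        y = ds.labels.ravel()
        clf = train_fcnn(ff.profiles, y, FCNNConfig(seed=0))
        carbon_rows = ff.profiles[y == int(dsn.ClassLabel.carbon)]
        pred = clf.predict(carbon_rows)
        assert (pred == int(dsn.ClassLabel.carbon)).mean() > 0.9

    def test_validation_accuracy_on_clean_data(self, small_geom, small_models):
        # a scan whose regions are large relative to the mixed band (the
        # realistic regime) separates cleanly within a session
        from diffscan.pipeline import extract_features

        scene = dsn.SceneSpec(grid_shape=(24, 24), regions=[
            (dsn.ClassLabel.amorphous_ice, [(2.6, 2.6), (13.4, 1.8), (14.2, 13.4), (3.4, 14.6)]),
            (dsn.ClassLabel.crystalline_ice, [(16.5, 16.5), (22.4, 16.8), (22.4, 22.4), (16.8, 22.4)]),
        ], mixed_band=1)
        ds = dsn.simulate_scan(scene, small_models, small_geom,
                               dsn.ScanGeometry(grid_shape=(24, 24)), seed=9,
                               drift_px=(1.5, -1.0))
        ff = extract_features(ds, crop_radius=None)
        X, y = ff.profiles, ds.labels.ravel()
        (X_tr, y_tr), (X_val, y_val), _ = split_datasets({"s": (X, y)}, SplitSpec(seed=0))
        clf = train_fcnn(X_tr, y_tr, FCNNConfig(seed=0))
        pure = y_val < 3
        acc = (clf.predict(X_val[pure]) == y_val[pure]).mean()
        assert acc >= 0.95

    def test_fcnn_svm_agree_on_separable_data(self, ria_training_data):
        X, y = ria_training_data
        fcnn = train_fcnn(X, y, FCNNConfig(seed=0))
        svm = train_svm(X, y, SVMConfig(seed=0))
        pure = y < 3
        agree = (fcnn.predict(X[pure]) == svm.predict(X[pure])).mean()
        assert agree >= 0.90

    def test_save_load_bit_identical(self, ria_training_data, tmp_path):
        X, y = ria_training_data
        clf = train_svm(X, y, SVMConfig(seed=0))
        clf.save(tmp_path / "svm.joblib")
        back = load_classifier(tmp_path / "svm.joblib")
        np.testing.assert_array_equal(clf.predict(X[:100]), back.predict(X[:100]))

    def test_predict_map_contract(self, ria_training_data):
        X, y = ria_training_data
        clf = train_fcnn(X, y, FCNNConfig(seed=0))
        labels, scores = predict_map(clf, X, (16, 16))
        assert labels.shape == (16, 16)
        assert scores.shape[:2] == (16, 16)
        np.testing.assert_allclose(scores.sum(axis=-1), 1.0, atol=1e-6)
        with pytest.raises(ValueError):
            predict_map(clf, X[:100], (16, 16))


class TestCenteringDegradation:
    def test_uncorrected_center_error_reduces_accuracy(self, small_scan, small_features):
        """Shifting every assumed centre by +5 px strictly degrades an RIA
        classifier; re-running centre refinement restores the accuracy."""
        from diffscan.pipeline import extract_features

        y = small_scan.labels.ravel()
        clf = train_fcnn(small_features.profiles, y, FCNNConfig(seed=0))
        acc_refined = (clf.predict(small_features.profiles) == y).mean()
        shifted = small_scan.true_centers + 5.0
        ff_bad = extract_features(small_scan, crop_radius=None, center_override=shifted)
        acc_bad = (clf.predict(ff_bad.profiles) == y).mean()
        assert acc_bad < acc_refined
        ff_again = extract_features(small_scan, crop_radius=None)
        acc_again = (clf.predict(ff_again.profiles) == y).mean()
        assert acc_again == pytest.approx(acc_refined, abs=0.02)


class TestCNN:
    @pytest.fixture(scope="class")
    def crop_data(self, small_scan, small_features):
        return small_features.crops, small_scan.labels.ravel()

    def test_architecture_constraints(self):
        with pytest.raises(ValueError):
            CNNConfig(channels=(8, 8, 16))
        with pytest.raises(ValueError):
            CNNConfig(dropout=1.0)

    def test_training_loss_decreases(self, crop_data):
        crops, y = crop_data
        cfg = CNNConfig(crop_radius=37, downsample=3, max_epochs=8, patience=8, seed=0,
                        channels=(4, 4, 8, 8, 16, 16))
        clf = train_cnn(crops, y, cfg)
        losses = [h["train_loss"] for h in clf.net.history]
        assert losses[-1] < losses[0]

    def test_deterministic_given_seed(self, crop_data):
        crops, y = crop_data
        cfg = CNNConfig(crop_radius=37, downsample=3, max_epochs=2, patience=5, seed=11,
                        channels=(4, 4, 8, 8, 16, 16))
        p1 = train_cnn(crops[:120], y[:120], cfg).predict(crops[120:160])
        p2 = train_cnn(crops[:120], y[:120], cfg).predict(crops[120:160])
        np.testing.assert_array_equal(p1, p2)

    def test_save_load_bit_identical(self, crop_data, tmp_path):
        crops, y = crop_data
        cfg = CNNConfig(crop_radius=37, downsample=3, max_epochs=3, patience=5, seed=0,
                        channels=(4, 4, 8, 8, 16, 16))
        clf = train_cnn(crops, y, cfg)
        clf.save(tmp_path / "cnn.joblib")
        back = load_classifier(tmp_path / "cnn.joblib")
        np.testing.assert_array_equal(clf.predict(crops[:100]), back.predict(crops[:100]))
        np.testing.assert_allclose(clf.predict_proba(crops[:20]), back.predict_proba(crops[:20]), atol=1e-6)

    def test_scores_sum_to_one(self, crop_data):
        crops, y = crop_data
        cfg = CNNConfig(crop_radius=37, downsample=3, max_epochs=2, patience=5, seed=0,
                        channels=(4, 4, 8, 8, 16, 16))
        clf = train_cnn(crops, y, cfg)
        proba = clf.predict_proba(crops[:50])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
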