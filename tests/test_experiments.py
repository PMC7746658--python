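"""Four-regime protocol: per-epoch composition, regime audits, smoke runs."""

import numpy as np
import pytest

from leafgan import benchmarks as B
from leafgan import LeafDatasetSpec, generate_dataset
from leafgan.augment import AugmentConfig
from leafgan.experiments import (RegimeSpec, SuiteConfig, compose_epoch_dataset,
                                 run_experiment_suite, train_classifier)
from leafgan.gan import GanTrainConfig, init_gan_state
from leafgan.losses import LsrParams


def _regime(reg, **kw):
    base = dict(regime=reg, epochs=2, batch_size=20, learning_rate=1e-4,
                n_synthetic_per_class=30, classifier_channels=2, seed=0,
                augment=AugmentConfig(seed=0))
    base.update(kw)
    return RegimeSpec(**base)


@pytest.fixture(scope="module")
def full_count_data():
    # 38 classes with the published 10-28 per-class counts (873 total)
    spec = LeafDatasetSpec(n_classes=38, n_per_class_train=1,
                           n_per_class_test=1, image_size=16,
                           feature_strength=1.0, seed=0,
                           train_counts=B.TRAIN_COUNTS_38)
    train, _ = generate_dataset(spec)
    return train


@pytest.fixture(scope="module")
def untrained_gan_38(full_count_data):
    cfg = GanTrainConfig(image_size=16, n_classes=38, noise_dim=16,
                         base_channels=2, batch_size=8,
                         lsr=LsrParams(0.22, 38), seed=0)
    return init_gan_state(cfg, full_count_data.class_names)


class TestComposition:
    """Per-epoch counts match the published composition for every regime."""

    def test_regime_i_is_873_originals(self, full_count_data):
        assert len(full_count_data) == 873
        ds, counts = compose_epoch_dataset(full_count_data, _regime("I"),
                                           None, epoch=0)
        assert counts == (873, 0, 0)
        assert ds.images is full_count_data.images

    def test_regime_ii_is_873_augmented(self, full_count_data):
        _, counts = compose_epoch_dataset(full_count_data, _regime("II"),
                                          None, epoch=0)
        assert counts == (0, 873, 0)

    @pytest.mark.parametrize("reg", ["III", "IV"])
    def test_regimes_iii_iv_add_30_per_class(self, full_count_data,
                                             untrained_gan_38, reg):
        ds, counts = compose_epoch_dataset(
            full_count_data, _regime(reg, labeling="conditioning"),
            untrained_gan_38, epoch=0)
        assert counts == (0, 873, 30 * 38)
        assert len(ds) == 873 + 1140

    def test_synthetic_images_regenerated_each_epoch(self, full_count_data,
                                                     untrained_gan_38):
        reg = _regime("III", labeling="conditioning", n_synthetic_per_class=2)
        a, _ = compose_epoch_dataset(full_count_data, reg, untrained_gan_38, 0)
        b, _ = compose_epoch_dataset(full_count_data, reg, untrained_gan_38, 1)
        assert not np.array_equal(a.images[-76:], b.images[-76:])

    def test_gan_required_for_regime_iii(self, full_count_data):
        with pytest.raises(ValueError, match="trained GAN"):
            compose_epoch_dataset(full_count_data, _regime("III"), None, 0)

    def test_regime_ii_with_zero_ranges_passes_originals_through(
            self, full_count_data):
        identity = AugmentConfig(rotation_range=0, width_shift_range=0,
                                 height_shift_range=0, zoom_range=0,
                                 horizontal_flip=False, vertical_flip=False)
        ds, _ = compose_epoch_dataset(full_count_data, _regime("II", augment=identity),
                                      None, epoch=0)
        assert np.array_equal(ds.images, full_count_data.images)


class TestTrainClassifier:
    def test_zero_epochs_reports_chance_level(self, leaf_data_32):
        train, test = leaf_data_32
        rep = train_classifier(train, test, _regime("I", epochs=0))
        # untrained network: accuracy within binomial error of 1/K
        assert abs(rep.final_test_accuracy - 0.5) <= 3 * np.sqrt(0.25 / len(test))

    def test_same_seed_gives_identical_curves(self, leaf_data_32):
        train, test = leaf_data_32
        a = train_classifier(train, test, _regime("II", epochs=2))
        b = train_classifier(train, test, _regime("II", epochs=2))
        assert a.train_curve == b.train_curve
        assert a.test_curve == b.test_curve

    def test_smoke_run_beats_chance_on_training_data(self, leaf_data_32):
        train, test = leaf_data_32
        rep = train_classifier(train, test, _regime("II", epochs=12,
                                                    classifier_channels=4))
        assert rep.final_train_accuracy > 0.5
        assert rep.confusion.total == len(test)

    def test_composition_log_matches_regime_every_epoch(self, leaf_data_32):
        train, test = leaf_data_32
        rep = train_classifier(train, test, _regime("II", epochs=3))
        assert rep.composition_log == [(0, len(train), 0)] * 3


@pytest.fixture(scope="module")
def tiny_suite():
    spec = LeafDatasetSpec(n_classes=2, n_per_class_train=10,
                           n_per_class_test=10, image_size=32,
                           feature_strength=1.0, seed=2)
    train, test = generate_dataset(spec)
    gan = GanTrainConfig(image_size=32, n_classes=2, noise_dim=16,
                         base_channels=2, batch_size=8, total_iterations=3,
                         lsr=LsrParams(0.22, 2), learning_rate=2e-4, seed=0)
    cfg = SuiteConfig(epochs=2, batch_size=10, learning_rate=1e-4,
                      n_synthetic_per_class=3, classifier_channels=2,
                      augment=AugmentConfig(seed=0), gan=gan, seed=0)
    return run_experiment_suite(train, test, cfg), test


class TestSuite:

    def test_exactly_four_reports_on_identical_test_set(self, tiny_suite):
        result, test = tiny_suite
        assert sorted(result.reports) == ["I", "II", "III", "IV"]
        hashes = {r.test_set_sha256 for r in result.reports.values()}
        assert len(hashes) == 1   # byte-identical test set everywhere

    def test_comparison_rows_ordered_i_to_iv(self, tiny_suite):
        result, _ = tiny_suite
        assert result.comparison["regime"].tolist() == ["I", "II", "III", "IV"]
        assert set(result.comparison.columns) == {
            "regime", "training_accuracy", "test_accuracy"}

    def test_regime_iii_iv_gan_configs_differ_only_in_epsilon(self, tiny_suite):
        result, _ = tiny_suite
        a, b = result.gan_config_iii, result.gan_config_iv
        da, db = a.to_dict(), b.to_dict()
        assert da.pop("lsr") == {"epsilon": 0.0, "n_classes": 2}
        assert db.pop("lsr") == {"epsilon": 0.22, "n_classes": 2}
        assert da == db


def test_regime_spec_validation():
    with pytest.raises(ValueError):
        _regime("V")
    with pytest.raises(ValueError):
        _regime("I", epochs=-1)
    with pytest.raises(ValueError):
        _regime("I", learning_rate=0.0)
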