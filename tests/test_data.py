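"""Synthetic leaf generator: determinism, class separability, splits, I/O."""

import numpy as np
import pytest
from matplotlib.colors import rgb_to_hsv

from leafgan import (LabeledImageSet, LeafDatasetSpec, generate_dataset,
                     generate_leaf_image, load_labeled_directory,
                     save_labeled_directory, split_labeled_directory)
from leafgan.data import split_counts


def _spec(**kw):
    base = dict(n_classes=2, n_per_class_train=5, n_per_class_test=5,
                image_size=32, feature_strength=1.0, seed=0)
    base.update(kw)
    return LeafDatasetSpec(**base)


class TestGenerateLeafImage:
    def test_bit_identical_under_repeated_calls(self):
        a = generate_leaf_image(0, _spec(), 7)
        b = generate_leaf_image(0, _spec(), 7)
        assert a.dtype == np.uint8 and a.shape == (32, 32, 3)
        assert np.array_equal(a, b)

    def test_zero_strength_makes_classes_pixel_identical(self):
        spec = _spec(feature_strength=0.0)
        assert np.array_equal(generate_leaf_image(0, spec, 3),
                              generate_leaf_image(1, spec, 3))

    def test_class_hue_separation_exceeds_three_sigma(self):
        """Mean-hue gap between two classes at full strength vs within-class
        spread, on 200 draws per class (the generator's hue parameterization
        places class hues 0.425 apart for K=2, far above the 0.01 jitter)."""
        spec = _spec(feature_strength=1.0)

        def mean_hue(img):
            return rgb_to_hsv(img / 255.0)[..., 0].mean()

        h0 = [mean_hue(generate_leaf_image(0, spec, i)) for i in range(200)]
        h1 = [mean_hue(generate_leaf_image(1, spec, 1000 + i)) for i in range(200)]
        gap = abs(np.mean(h0) - np.mean(h1))
        assert gap > 3 * max(np.std(h0), np.std(h1))

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            generate_leaf_image(2, _spec(), 0)


class TestGenerateDataset:
    def test_bookkeeping_38_classes(self):
        spec = _spec(n_classes=38, n_per_class_train=10, n_per_class_test=1,
                     image_size=16)
        train, test = generate_dataset(spec)
        assert len(train) == 380
        assert len(test) == 38
        assert np.array_equal(np.bincount(train.labels), np.full(38, 10))

    def test_identical_spec_gives_identical_data(self):
        t1, _ = generate_dataset(_spec())
        t2, _ = generate_dataset(_spec())
        assert np.array_equal(t1.labels, t2.labels)
        assert np.array_equal(t1.images, t2.images)

    def test_train_and_test_share_no_image(self):
        train, test = generate_dataset(_spec())
        train_bytes = {im.tobytes() for im in train.images}
        assert all(im.tobytes() not in train_bytes for im in test.images)

    def test_unbalanced_train_counts(self):
        spec = _spec(n_classes=3, train_counts=(3, 7, 5))
        train, _ = generate_dataset(spec)
        assert np.bincount(train.labels).tolist() == [3, 7, 5]

    def test_tiny_classifier_separates_full_strength_classes(self):
        """50/class at strength 1.0: logistic regression on raw pixels gets
        >0.9 held-out accuracy (pilot-chosen threshold)."""
        from sklearn.linear_model import LogisticRegression
        spec = _spec(n_per_class_train=50, n_per_class_test=25)
        train, test = generate_dataset(spec)
        clf = LogisticRegression(max_iter=2000).fit(
            train.images.reshape(len(train), -1) / 255.0, train.labels)
        acc = clf.score(test.images.reshape(len(test), -1) / 255.0, test.labels)
        assert acc > 0.9

    def test_separability_monotone_in_feature_strength(self):
        """Held-out accuracy of a fixed classifier is non-decreasing over
        strengths {0, 0.5, 1.0} (median over 3 seeds)."""
        from sklearn.linear_model import LogisticRegression
        accs = {}
        for strength in (0.0, 0.5, 1.0):
            runs = []
            for seed in (0, 1, 2):
                spec = _spec(n_per_class_train=25, n_per_class_test=15,
                             image_size=16, feature_strength=strength, seed=seed)
                train, test = generate_dataset(spec)
                clf = LogisticRegression(max_iter=1000).fit(
                    train.images.reshape(len(train), -1) / 255.0, train.labels)
                runs.append(clf.score(
                    test.images.reshape(len(test), -1) / 255.0, test.labels))
            accs[strength] = np.median(runs)
        assert accs[0.0] <= accs[0.5] + 1e-9 <= accs[1.0] + 2e-9


class TestLabeledImageSet:
    def test_length_and_label_consistency_enforced(self):
        imgs = np.zeros((3, 8, 8, 3), np.uint8)
        with pytest.raises(ValueError):
            LabeledImageSet(imgs, [0, 1], ["a", "b"])
        with pytest.raises(ValueError):
            LabeledImageSet(imgs, [0, 1, 5], ["a", "b"])

    def test_float_round_trip(self):
        imgs = np.arange(2 * 4 * 4 * 3, dtype=np.uint8).reshape(2, 4, 4, 3)
        ds = LabeledImageSet(imgs, [0, 1], ["a", "b"])
        f = ds.to_float()
        assert f.min() >= -1.0 and f.max() <= 1.0
        back = LabeledImageSet.from_float(f, ds.labels, ds.class_names)
        assert np.array_equal(back.images, imgs)


class TestDirectorySplit:
    @pytest.mark.parametrize("n,frac,expected", [
        (10, 0.8, (8, 2)),
        (10, 1.0, (10, 0)),
        (1, 0.5, (1, 0)),     # minimum one training image
        (2, 0.01, (1, 1)),    # at least one on each side when possible
        (5, 0.99, (4, 1)),    # fraction < 1 keeps a test image
    ])
    def test_split_counts_rule(self, n, frac, expected):
        assert split_counts(n, frac) == expected

    def test_small_fraction_of_large_tree_approximates_fraction(self):
        """Per-class floor rounding of 1.9% over a 43,843-image tree of 38
        classes lands within one image per class of the exact fraction
        (independent oracle: sum the per-class floors directly)."""
        rng = np.random.default_rng(0)
        sizes = rng.multinomial(43843, np.ones(38) / 38)
        expected = sum(max(1, int(np.floor(0.019 * n))) for n in sizes)
        assert abs(expected - 0.019 * 43843) <= 38
        assert sum(split_counts(n, 0.019)[0] for n in sizes) == expected

    def test_directory_round_trip_and_split_partition(self, tmp_path):
        spec = _spec(n_per_class_train=10, image_size=16)
        train, _ = generate_dataset(spec)
        save_labeled_directory(train, tmp_path, spec=spec, split_name="train")
        loaded = load_labeled_directory(tmp_path)
        assert len(loaded) == len(train)
        assert sorted(loaded.class_names) == sorted(train.class_names)

        tr, te = split_labeled_directory(tmp_path, 0.8, seed=0)
        assert len(tr) == 16 and len(te) == 4   # 8/2 per class
        # partition: byte-sets unite to the full set
        all_imgs = {im.tobytes() for im in loaded.images}
        got = {im.tobytes() for im in tr.images} | {im.tobytes() for im in te.images}
        assert got == all_imgs

    def test_split_deterministic_under_seed(self, tmp_path):
        train, _ = generate_dataset(_spec(n_per_class_train=6, image_size=16))
        save_labeled_directory(train, tmp_path)
        a_tr, _ = split_labeled_directory(tmp_path, 0.5, seed=3)
        b_tr, _ = split_labeled_directory(tmp_path, 0.5, seed=3)
        assert np.array_equal(a_tr.images, b_tr.images)

    def test_full_fraction_warns_on_empty_test(self, tmp_path):
        train, _ = generate_dataset(_spec(image_size=16))
        save_labeled_directory(train, tmp_path)
        with pytest.warns(UserWarning, match="empty test"):
            _, te = split_labeled_directory(tmp_path, 1.0, seed=0)
        assert len(te) == 0

    def test_unreadable_file_reported_with_path(self, tmp_path):
        train, _ = generate_dataset(_spec(image_size=16))
        save_labeled_directory(train, tmp_path)
        bad = tmp_path / train.class_names[0] / "broken.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(ValueError, match="broken.png"):
            load_labeled_directory(tmp_path)
        loaded = load_labeled_directory(tmp_path, skip_unreadable=True)
        assert len(loaded) == len(train)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            _spec(n_classes=1)
        with pytest.raises(ValueError):
            _spec(image_size=8)
        with pytest.raises(ValueError):
            _spec(feature_strength=1.5)
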