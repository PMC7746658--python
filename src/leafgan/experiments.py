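"""The four-regime comparison protocol and classifier training.

Regimes (per-epoch data composition, N = training-set size, K = classes,
m = synthetic images per class):

    I    N original images, nothing else
    II   N classic-augmented images (fresh transforms every epoch)
    III  N classic-augmented + m·K synthetic images from a WGAN-GP whose
         class loss uses plain cross-entropy (smoothing eps = 0)
    IV   as III but the GAN's class loss is label-smoothed (eps = 0.22)

The classifier is the VGG16-style network trained with RMSprop on plain
cross-entropy; synthetic images are regenerated every epoch from the
trained generator, mirroring the full-scale procedure.  Training accuracy
is measured on the composed (augmented + synthetic) epoch data as it is
seen; test accuracy on the fixed held-out set after every epoch.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_batch
from .data import LabeledImageSet
from .evaluation import (ClassMetrics, ConfusionMatrix, confusion_matrix,
                         per_class_metrics)
from .gan import (GanTrainConfig, GanTrainState, synthesize_labeled_images,
                  train_wgan_gp_lsr)
from .layers import RMSprop
from .losses import LsrParams, class_nll_batch
from .networks import Classifier, NetworkSpec, build_classifier
from .tensor import Tensor, grad

__all__ = ["RegimeSpec", "ExperimentReport", "SuiteConfig",
           "compose_epoch_dataset", "train_classifier",
           "run_experiment_suite"]

REGIMES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class RegimeSpec:
    """One training regime.  Full-scale protocol: 700 epochs, batch 100,
    RMSprop learning rate 1e-4, 30 synthetic images per class."""

    regime: str
    epochs: int = 700
    batch_size: int = 100
    learning_rate: float = 1e-4
    n_synthetic_per_class: int = 30
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    labeling: str = "discriminator_argmax"
    classifier_channels: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def uses_gan(self) -> bool:
        return self.regime in ("III", "IV")


@dataclass
class ExperimentReport:
    """Everything the comparison tables need for one regime."""

    regime: str
    final_train_accuracy: float
    final_test_accuracy: float
    train_curve: List[float]
    test_curve: List[float]
    confusion: ConfusionMatrix
    per_class: List[ClassMetrics]
    composition_log: List[Tuple[int, int, int]]
    test_set_sha256: str

    def __post_init__(self):
        if not (0.0 <= self.final_train_accuracy <= 1.0
                and 0.0 <= self.final_test_accuracy <= 1.0):
            raise ValueError("accuracies must lie in [0, 1]")


def _dataset_hash(ds: LabeledImageSet) -> str:
    h = hashlib.sha256()
    h.update(ds.images.tobytes())
    h.update(ds.labels.tobytes())
    return h.hexdigest()


def compose_epoch_dataset(train_set: LabeledImageSet, regime: RegimeSpec,
                          gan_state: Optional[GanTrainState], epoch: int
                          ) -> Tuple[LabeledImageSet, Tuple[int, int, int]]:
    """Assemble one epoch's training data per the regime's composition row.

    Returns the dataset and the count triple (original, classic-augmented,
    synthetic).  Regimes III/IV synthesize fresh images per epoch.
    """
    if regime.uses_gan and gan_state is None:
        raise ValueError(f"regime {regime.regime} needs a trained GAN state")
    if regime.regime == "I":
        return train_set, (len(train_set), 0, 0)
    aug = augment_batch(train_set, regime.augment,
                        epoch_seed=_epoch_seed(regime.seed, epoch))
    if regime.regime == "II":
        return aug, (0, len(aug), 0)
    synth = synthesize_labeled_images(gan_state, regime.n_synthetic_per_class,
                                      labeling=regime.labeling, seed=epoch)
    return aug.concat(synth), (0, len(aug), len(synth))


def _epoch_seed(seed: int, epoch: int) -> int:
    # distinct stream per (run seed, epoch), kept below 2**31
    return int(np.random.SeedSequence(
        entropy=seed, spawn_key=(epoch,)).generate_state(1)[0] % (2 ** 31))


def train_classifier(train_set: LabeledImageSet, test_set: LabeledImageSet,
                     regime: RegimeSpec,
                     gan_state: Optional[GanTrainState] = None
                     ) -> ExperimentReport:
    """Train the classifier under one regime and evaluate per epoch."""
    if train_set.image_size != test_set.image_size:
        raise ValueError("train/test image sizes differ")
    if train_set.class_names != test_set.class_names:
        raise ValueError("train/test class maps differ")
    K = train_set.n_classes
    spec = NetworkSpec("classifier", train_set.image_size, K,
                       base_channels=regime.classifier_channels)
    model = build_classifier(spec, seed=regime.seed)
    opt = RMSprop(model.params(), regime.learning_rate)

    train_curve: List[float] = []
    test_curve: List[float] = []
    composition: List[Tuple[int, int, int]] = []
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=regime.seed, spawn_key=(9,)))

    for epoch in range(regime.epochs):
        epoch_data, counts = compose_epoch_dataset(
            train_set, regime, gan_state, epoch)
        composition.append(counts)
        order = shuffle_rng.permutation(len(epoch_data))
        x = epoch_data.to_float()[order]
        y = epoch_data.labels[order]
        hits = 0
        for i in range(0, len(y), regime.batch_size):
            xb, yb = x[i:i + regime.batch_size], y[i:i + regime.batch_size]
            probs = model.forward(Tensor(xb), train=True)
            loss = class_nll_batch(probs, yb)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite classifier loss at epoch {epoch}")
            hits += int((np.argmax(probs.data, axis=1) == yb).sum())
            opt.step(grad(loss, model.params()))
        train_curve.append(hits / len(y))
        test_curve.append(_accuracy(model, test_set))

    if regime.epochs == 0:
        train_curve.append(_accuracy(model, train_set))
        test_curve.append(_accuracy(model, test_set))
        composition.append((len(train_set), 0, 0) if regime.regime == "I"
                           else (0, len(train_set),
                                 regime.n_synthetic_per_class * K
                                 if regime.uses_gan else 0))

    preds = model.predict(test_set.to_float())
    cm = confusion_matrix(test_set.labels, preds, K, test_set.class_names)
    return ExperimentReport(
        regime=regime.regime,
        final_train_accuracy=train_curve[-1],
        final_test_accuracy=test_curve[-1],
        train_curve=train_curve,
        test_curve=test_curve,
        confusion=cm,
        per_class=per_class_metrics(cm),
        composition_log=composition,
        test_set_sha256=_dataset_hash(test_set),
    )


def _accuracy(model: Classifier, ds: LabeledImageSet) -> float:
    preds = model.predict(ds.to_float())
    return float(np.mean(preds == ds.labels))


@dataclass(frozen=True)
class SuiteConfig:
    """Configuration shared by the four regimes of one comparison suite.

    The two GAN runs (for regimes III and IV) differ only in the smoothing
    weight: eps = 0 for III, ``lsr_epsilon`` (default 0.22) for IV.
    """

    epochs: int = 700
    batch_size: int = 100
    learning_rate: float = 1e-4
    n_synthetic_per_class: int = 30
    classifier_channels: int = 64
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    gan: GanTrainConfig = field(default_factory=GanTrainConfig)
    lsr_epsilon: float = 0.22
    labeling: str = "discriminator_argmax"
    seed: int = 0


@dataclass
class SuiteResult:
    reports: Dict[str, ExperimentReport]
    comparison: pd.DataFrame
    gan_config_iii: GanTrainConfig
    gan_config_iv: GanTrainConfig


def run_experiment_suite(train_set: LabeledImageSet,
                         test_set: LabeledImageSet,
                         config: SuiteConfig) -> SuiteResult:
    """Run regimes I-IV on identical data and emit the comparison table.

    The GAN for III is trained with plain cross-entropy class loss, the GAN
    for IV with label smoothing; both are trained on the classic-augmented
    stream, and all four regimes score the byte-identical test set.
    """
    K = train_set.n_classes
    gan_iii_cfg = replace(config.gan, n_classes=K,
                          image_size=train_set.image_size,
                          lsr=LsrParams(0.0, K),
                          augment=config.augment, seed=config.seed)
    gan_iv_cfg = replace(gan_iii_cfg, lsr=LsrParams(config.lsr_epsilon, K))
    gan_iii = train_wgan_gp_lsr(train_set, gan_iii_cfg)
    gan_iv = train_wgan_gp_lsr(train_set, gan_iv_cfg)

    reports: Dict[str, ExperimentReport] = {}
    for regime_name, gan_state in (("I", None), ("II", None),
                                   ("III", gan_iii), ("IV", gan_iv)):
        regime = RegimeSpec(
            regime=regime_name, epochs=config.epochs,
            batch_size=config.batch_size, learning_rate=config.learning_rate,
            n_synthetic_per_class=config.n_synthetic_per_class,
            augment=config.augment, labeling=config.labeling,
            classifier_channels=config.classifier_channels, seed=config.seed)
        reports[regime_name] = train_classifier(
            train_set, test_set, regime, gan_state)

    comparison = pd.DataFrame(
        [{"regime": r,
          "training_accuracy": reports[r].final_train_accuracy,
          "test_accuracy": reports[r].final_test_accuracy}
         for r in REGIMES])
    return SuiteResult(reports=reports, comparison=comparison,
                       gan_config_iii=gan_iii_cfg, gan_config_iv=gan_iv_cfg)
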