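"""The conditional WGAN-GP-LSR training loop and labeled-image synthesis.

One *iteration* = ``critic_steps_per_gen_step`` critic updates followed by
one generator update.  The critic is trained on the Wasserstein loss (real
labeled +1, synthetic −1 — i.e. −mean(real score) + mean(fake score)), the
two-sided gradient penalty on uniform interpolates, and a label-smoothed
cross-entropy on the class head for real labeled images.  The generator
(and its label embedding) is trained to raise the critic's validity score
of its samples and to make the class head assign the smoothed conditioning
label.  Real batches may be streamed through classic augmentation, which is
how the full-scale protocol feeds its GAN.

Everything is deterministic under the config seed: per-step randomness
comes from counter-based ``SeedSequence`` keys, so two runs with identical
config and data produce bit-identical weights and histories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .augment import AugmentConfig, augment_batch
from .data import LabeledImageSet
from .layers import RMSprop, frozen_batch_stats
from .losses import (GpParams, LsrParams, gradient_penalty, lsr_loss_batch,
                     wasserstein_critic_loss, wasserstein_generator_loss)
from .networks import (Discriminator, Generator, NetworkSpec,
                       build_discriminator, build_generator)
from .tensor import Tensor, grad, no_grad, softmax

__all__ = ["GanTrainConfig", "GanTrainState", "GanDivergenceError",
           "init_gan_state", "critic_step", "generator_step",
           "train_wgan_gp_lsr", "synthesize_labeled_images",
           "save_checkpoint", "load_checkpoint", "history_to_frame"]

logger = logging.getLogger(__name__)

HISTORY_FIELDS = ("iteration", "critic_loss", "gen_loss",
                  "wasserstein_estimate", "class_loss_real", "class_loss_fake")


class GanDivergenceError(RuntimeError):
    """Raised when a training loss turns non-finite; carries the diagnostic
    record of the offending step."""

    def __init__(self, message: str, record: dict):
        super().__init__(f"{message}; diagnostic record: {record}")
        self.record = record


@dataclass(frozen=True)
class GanTrainConfig:
    """All GAN hyperparameters.

    Full-scale values: RMSprop at learning rate 5e-5, a 1000-d noise input,
    smoothing weight eps = 0.22, penalty weight 10, roughly 22,000
    iterations at 128×128.  ``image_size``/``base_channels`` scale the
    networks down for CPU-sized runs.
    """

    image_size: int = 32
    n_classes: int = 2
    learning_rate: float = 5e-5
    batch_size: int = 32
    critic_steps_per_gen_step: int = 5
    total_iterations: int = 500
    lambda_gp: float = 10.0
    lsr: LsrParams = field(default_factory=lambda: LsrParams(0.22, 2))
    noise_dim: int = 1000
    base_channels: int = 16
    class_loss_weight: float = 1.0
    noise_dist: str = "normal"       # "normal" (default) or "uniform"
    augment: Optional[AugmentConfig] = None
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: Optional[str] = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("batch_size", "critic_steps_per_gen_step", "noise_dim",
                     "base_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.total_iterations < 0:
            raise ValueError("total_iterations must be >= 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (interpolation pairs)")
        if self.lambda_gp < 0:
            raise ValueError("lambda_gp must be >= 0")
        if self.noise_dist not in ("normal", "uniform"):
            raise ValueError("noise_dist must be 'normal' or 'uniform'")
        if self.lsr.n_classes != self.n_classes:
            raise ValueError("lsr.n_classes must equal n_classes")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("image_size", "n_classes", "learning_rate", "batch_size",
              "critic_steps_per_gen_step", "total_iterations", "lambda_gp",
              "noise_dim", "base_channels", "class_loss_weight", "noise_dist",
              "seed", "checkpoint_every", "checkpoint_dir")}
        d["lsr"] = {"epsilon": self.lsr.epsilon, "n_classes": self.lsr.n_classes}
        d["augment"] = self.augment.to_dict() if self.augment else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GanTrainConfig":
        d = dict(d)
        d["lsr"] = LsrParams(**d["lsr"])
        if d.get("augment"):
            d["augment"] = AugmentConfig.from_dict(d["augment"])
        return cls(**d)


@dataclass
class GanTrainState:
    """Mutable training state: the two networks, their optimizers, counters
    and the per-iteration loss history."""

    generator: Generator
    discriminator: Discriminator
    g_opt: RMSprop
    d_opt: RMSprop
    config: GanTrainConfig
    class_names: List[str]
    iteration: int = 0
    critic_updates: int = 0
    generator_updates: int = 0
    history: List[dict] = field(default_factory=list)
    last_label_disagreement: Optional[float] = None


def init_gan_state(config: GanTrainConfig, class_names: List[str]) -> GanTrainState:
    gspec = NetworkSpec("generator", config.image_size, config.n_classes,
                        noise_dim=config.noise_dim,
                        base_channels=config.base_channels)
    dspec = NetworkSpec("discriminator", config.image_size, config.n_classes,
                        base_channels=config.base_channels)
    gen = build_generator(gspec, seed=config.seed)
    disc = build_discriminator(dspec, seed=config.seed + 1)
    return GanTrainState(
        generator=gen, discriminator=disc,
        g_opt=RMSprop(gen.params(), config.learning_rate),
        d_opt=RMSprop(disc.params(), config.learning_rate),
        config=config, class_names=list(class_names))


def _draw_noise(rng: np.random.Generator, n: int, dim: int, dist: str) -> np.ndarray:
    if dist == "uniform":
        return rng.uniform(-1.0, 1.0, (n, dim))
    return rng.standard_normal((n, dim))


def _check_finite(record: dict, where: str) -> None:
    bad = {k: v for k, v in record.items()
           if isinstance(v, float) and not np.isfinite(v)}
    if bad:
        raise GanDivergenceError(f"non-finite loss in {where}", record)


def critic_step(state: GanTrainState, real_batch: LabeledImageSet,
                config: GanTrainConfig, step_seed: int = 0) -> dict:
    """One optimizer update of the critic; the generator is untouched.

    Returns the loss record (also used for the iteration history).
    """
    if len(real_batch) < 2:
        raise ValueError("critic_step needs a batch of >= 2 images")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1, int(step_seed))))
    B = len(real_batch)
    real = Tensor(real_batch.to_float())
    z = _draw_noise(rng, B, config.noise_dim, config.noise_dist)
    fake_labels = rng.integers(0, config.n_classes, B)
    with frozen_batch_stats():
        fake = state.generator(z, fake_labels, train=True).detach()

    v_real, logits_real = state.discriminator(real, train=True)
    v_fake, _ = state.discriminator(fake, train=True)
    w_loss = wasserstein_critic_loss(v_real, v_fake)
    gp = gradient_penalty(state.discriminator, real, fake,
                          GpParams(config.lambda_gp), rng)
    cls_loss = lsr_loss_batch(softmax(logits_real), real_batch.labels, config.lsr)
    total = w_loss + gp + Tensor(config.class_loss_weight) * cls_loss

    record = {
        "critic_loss": total.item(),
        "wasserstein_estimate": -w_loss.item(),
        "gradient_penalty": gp.item(),
        "class_loss_real": cls_loss.item(),
    }
    _check_finite(record, "critic_step")
    grads = grad(total, state.discriminator.params())
    state.d_opt.step(grads)
    state.critic_updates += 1
    return record


def generator_step(state: GanTrainState, config: GanTrainConfig,
                   step_seed: int = 0) -> dict:
    """One optimizer update of the generator and its label embedding; the
    critic is untouched."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2, int(step_seed))))
    B = config.batch_size
    z = _draw_noise(rng, B, config.noise_dim, config.noise_dist)
    labels = rng.integers(0, config.n_classes, B)
    fake = state.generator(z, labels, train=True)
    with frozen_batch_stats():
        v_fake, logits_fake = state.discriminator(fake, train=True)
    w_loss = wasserstein_generator_loss(v_fake)
    cls_loss = lsr_loss_batch(softmax(logits_fake), labels, config.lsr)
    total = w_loss + Tensor(config.class_loss_weight) * cls_loss

    record = {"gen_loss": total.item(), "class_loss_fake": cls_loss.item()}
    _check_finite(record, "generator_step")
    grads = grad(total, state.generator.params())
    state.g_opt.step(grads)
    state.generator_updates += 1
    return record


def train_wgan_gp_lsr(train_set: LabeledImageSet,
                      config: GanTrainConfig) -> GanTrainState:
    """Run the full adversarial loop on a labeled training set.

    Every class must be represented at least once.  When ``config.augment``
    is set, each real batch is replaced by a freshly transformed copy
    (streaming augmentation).  History holds one record per iteration.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    present = np.unique(train_set.labels)
    missing = sorted(set(range(config.n_classes)) - set(present.tolist()))
    if missing:
        raise ValueError(f"classes without training examples: {missing}")
    if train_set.image_size != config.image_size:
        raise ValueError("config.image_size does not match the data")

    state = init_gan_state(config, train_set.class_names)
    batch_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    n = len(train_set)
    for it in range(config.total_iterations):
        last_critic: dict = {}
        for k in range(config.critic_steps_per_gen_step):
            idx = batch_rng.choice(n, size=min(config.batch_size, n),
                                   replace=n < config.batch_size)
            batch = train_set.subset(idx)
            if config.augment is not None:
                batch = augment_batch(
                    batch, config.augment,
                    epoch_seed=it * config.critic_steps_per_gen_step + k)
            last_critic = critic_step(
                state, batch, config,
                step_seed=it * config.critic_steps_per_gen_step + k)
        gen_rec = generator_step(state, config, step_seed=it)
        state.iteration = it + 1
        state.history.append({
            "iteration": it + 1,
            "critic_loss": last_critic["critic_loss"],
            "gen_loss": gen_rec["gen_loss"],
            "wasserstein_estimate": last_critic["wasserstein_estimate"],
            "class_loss_real": last_critic["class_loss_real"],
            "class_loss_fake": gen_rec["class_loss_fake"],
        })
        if (config.checkpoint_every and config.checkpoint_dir
                and (it + 1) % config.checkpoint_every == 0):
            save_checkpoint(state, config.checkpoint_dir)
    return state


def synthesize_labeled_images(state: GanTrainState, n_per_class: int,
                              labeling: str = "discriminator_argmax",
                              seed: int = 0) -> LabeledImageSet:
    """Generate ``n_per_class`` images per class with the trained generator.

    ``labeling='conditioning'`` keeps the conditioning label of each image;
    ``'discriminator_argmax'`` (the default) relabels each image with the
    class of largest predicted probability, as the full-scale procedure
    describes.  The disagreement rate between the two labelings is logged
    and kept on ``state.last_label_disagreement``.
    """
    if labeling not in ("conditioning", "discriminator_argmax"):
        raise ValueError("labeling must be 'conditioning' or 'discriminator_argmax'")
    config = state.config
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(3, int(seed))))
    cond_labels = np.repeat(np.arange(config.n_classes), n_per_class)
    z = _draw_noise(rng, len(cond_labels), config.noise_dim, config.noise_dist)
    images, argmax_labels = [], []
    with no_grad():
        for i in range(0, len(cond_labels), config.batch_size):
            zb, lb = z[i:i + config.batch_size], cond_labels[i:i + config.batch_size]
            fake = state.generator(zb, lb, train=False)
            probs = state.discriminator.class_probabilities(fake, train=False)
            images.append(fake.data)
            argmax_labels.append(np.argmax(probs.data, axis=1))
    images = np.concatenate(images)
    argmax_labels = np.concatenate(argmax_labels)
    disagreement = float(np.mean(argmax_labels != cond_labels))
    state.last_label_disagreement = disagreement
    logger.info("conditioning vs argmax label disagreement: %.3f", disagreement)
    final = cond_labels if labeling == "conditioning" else argmax_labels
    return LabeledImageSet.from_float(images, final, state.class_names)


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(state: GanTrainState, directory) -> Path:
    """Write iteration-stamped weights (npz) plus a JSON sidecar with the
    config, class names and counters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"gan_iter{state.iteration:07d}"
    flat = {}

    def _flatten(prefix, d):
        for k, v in d.items():
            if isinstance(v, dict):
                _flatten(f"{prefix}{k}/", v)
            else:
                flat[f"{prefix}{k}"] = v

    _flatten("G/", state.generator.state())
    _flatten("D/", state.discriminator.state())
    _flatten("gopt/", state.g_opt.state())
    _flatten("dopt/", state.d_opt.state())
    np.savez(directory / f"{stem}.npz",
             **{k: np.asarray(v) for k, v in flat.items()})
    sidecar = {
        "iteration": state.iteration,
        "critic_updates": state.critic_updates,
        "generator_updates": state.generator_updates,
        "config": state.config.to_dict(),
        "class_names": state.class_names,
        "history": state.history,
        "last_label_disagreement": state.last_label_disagreement,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar))
    return directory / f"{stem}.npz"


def load_checkpoint(npz_path) -> GanTrainState:
    npz_path = Path(npz_path)
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    config = GanTrainConfig.from_dict(sidecar["config"])
    state = init_gan_state(config, sidecar["class_names"])
    arrays = np.load(npz_path)

    def _unflatten(prefix):
        out: dict = {}
        for key in arrays.files:
            if not key.startswith(prefix):
                continue
            parts = key[len(prefix):].split("/")
            d = out
            for p in parts[:-1]:
                d = d.setdefault(p, {})
            d[parts[-1]] = arrays[key]
        return out

    state.generator.load_state(_unflatten("G/"))
    state.discriminator.load_state(_unflatten("D/"))
    state.g_opt.load_state(_unflatten("gopt/"))
    state.d_opt.load_state(_unflatten("dopt/"))
    state.iteration = sidecar["iteration"]
    state.critic_updates = sidecar["critic_updates"]
    state.generator_updates = sidecar["generator_updates"]
    state.history = sidecar["history"]
    state.last_label_disagreement = sidecar.get("last_label_disagreement")
    return state


def history_to_frame(state: GanTrainState):
    """Loss history as a pandas DataFrame (one row per iteration)."""
    import pandas as pd
    return pd.DataFrame(state.history, columns=list(HISTORY_FIELDS))
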