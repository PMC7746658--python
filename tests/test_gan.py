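"""Adversarial training loop: step isolation, determinism, checkpoints,
labeled synthesis."""

import copy

import numpy as np
import pytest

from leafgan.data import LabeledImageSet
from leafgan.gan import (GanDivergenceError, GanTrainConfig, critic_step,
                         generator_step, init_gan_state, load_checkpoint,
                         save_checkpoint, synthesize_labeled_images,
                         train_wgan_gp_lsr, _check_finite)
from leafgan.losses import LsrParams


def _config(**kw):
    base = dict(image_size=16, n_classes=2, noise_dim=16, base_channels=2,
                batch_size=8, critic_steps_per_gen_step=2, total_iterations=5,
                lsr=LsrParams(0.22, 2), learning_rate=2e-4, seed=0)
    base.update(kw)
    return GanTrainConfig(**base)


def _weights(net):
    return [p.data.copy() for p in net.params()]


def _same(a, b):
    return all(np.array_equal(x, y) for x, y in zip(a, b))


@pytest.fixture()
def state_and_batch(tiny_leaf_data):
    train, _ = tiny_leaf_data
    cfg = _config()
    state = init_gan_state(cfg, train.class_names)
    return state, train.subset(np.arange(8)), cfg


class TestCriticStep:
    def test_zero_learning_rate_leaves_weights_unchanged(self, state_and_batch):
        state, batch, cfg = state_and_batch
        state.d_opt.lr = 0.0
        before = _weights(state.discriminator)
        rec = critic_step(state, batch, cfg, step_seed=0)
        assert _same(before, _weights(state.discriminator))
        assert all(np.isfinite(v) for v in rec.values())

    def test_deterministic_given_state_batch_and_seed(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        cfg = _config()
        batch = train.subset(np.arange(8))
        runs = []
        for _ in range(2):
            st = init_gan_state(cfg, train.class_names)
            critic_step(st, batch, cfg, step_seed=3)
            runs.append(_weights(st.discriminator))
        assert _same(*runs)

    def test_generator_untouched_including_buffers(self, state_and_batch):
        state, batch, cfg = state_and_batch
        g_before = _weights(state.generator)
        bn_before = [l.run_mean.copy() for l in state.generator.body.layers
                     if hasattr(l, "run_mean")]
        critic_step(state, batch, cfg, step_seed=0)
        assert _same(g_before, _weights(state.generator))
        bn_after = [l.run_mean for l in state.generator.body.layers
                    if hasattr(l, "run_mean")]
        assert _same(bn_before, bn_after)

    def test_tiny_batch_rejected(self, state_and_batch):
        state, batch, cfg = state_and_batch
        with pytest.raises(ValueError):
            critic_step(state, batch.subset([0]), cfg)


class TestGeneratorStep:
    def test_discriminator_untouched(self, state_and_batch):
        state, _, cfg = state_and_batch
        d_before = _weights(state.discriminator)
        generator_step(state, cfg, step_seed=0)
        assert _same(d_before, _weights(state.discriminator))

    def test_updates_embedding_with_generator(self, state_and_batch):
        state, _, cfg = state_and_batch
        emb_before = state.generator.embedding.table.data.copy()
        generator_step(state, cfg, step_seed=0)
        assert not np.array_equal(emb_before, state.generator.embedding.table.data)


class TestTrainLoop:
    def test_zero_iterations_returns_initial_state(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        st = train_wgan_gp_lsr(train, _config(total_iterations=0))
        assert st.iteration == 0 and st.history == []

    def test_identical_runs_are_bit_identical(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        a = train_wgan_gp_lsr(train, _config(total_iterations=3))
        b = train_wgan_gp_lsr(train, _config(total_iterations=3))
        assert _same(_weights(a.generator), _weights(b.generator))
        assert _same(_weights(a.discriminator), _weights(b.discriminator))
        assert a.history == b.history

    def test_smoke_run_records_finite_history(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        st = train_wgan_gp_lsr(train, _config(total_iterations=15))
        assert len(st.history) == 15
        for rec in st.history:
            for key in ("critic_loss", "gen_loss", "wasserstein_estimate",
                        "class_loss_real", "class_loss_fake"):
                assert np.isfinite(rec[key])

    def test_alternation_audit(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        cfg = _config(total_iterations=7, critic_steps_per_gen_step=3)
        st = train_wgan_gp_lsr(train, cfg)
        assert st.generator_updates == 7
        assert st.critic_updates == 3 * 7

    def test_missing_class_rejected_before_training(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        only_zero = train.subset(np.flatnonzero(train.labels == 0))
        with pytest.raises(ValueError, match="classes without"):
            train_wgan_gp_lsr(only_zero, _config())

    def test_streaming_augmentation_accepted(self, tiny_leaf_data):
        from leafgan.augment import AugmentConfig
        train, _ = tiny_leaf_data
        st = train_wgan_gp_lsr(train, _config(
            total_iterations=2, augment=AugmentConfig(seed=0)))
        assert len(st.history) == 2


class TestSynthesis:
    def test_conditioning_labels_are_exact_and_counts_match(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        st = train_wgan_gp_lsr(train, _config(total_iterations=2))
        synth = synthesize_labeled_images(st, 5, labeling="conditioning", seed=0)
        assert len(synth) == 10
        assert np.array_equal(synth.labels, np.repeat([0, 1], 5))
        assert st.last_label_disagreement is not None

    def test_untrained_argmax_agreement_is_near_chance(self, tiny_leaf_data):
        """With an uninformative critic the argmax label agrees with the
        conditioning label at roughly the 0.5 chance rate (200 draws)."""
        train, _ = tiny_leaf_data
        st = init_gan_state(_config(), train.class_names)
        synthesize_labeled_images(st, 100, labeling="discriminator_argmax", seed=1)
        agreement = 1.0 - st.last_label_disagreement
        assert 0.3 <= agreement <= 0.7

    def test_unknown_labeling_mode_rejected(self, tiny_leaf_data):
        train, _ = tiny_leaf_data
        st = init_gan_state(_config(), train.class_names)
        with pytest.raises(ValueError):
            synthesize_labeled_images(st, 1, labeling="oracle")


class TestCheckpoints:
    def test_round_trip_reproduces_synthesis(self, tiny_leaf_data, tmp_path):
        train, _ = tiny_leaf_data
        st = train_wgan_gp_lsr(train, _config(total_iterations=3))
        ref = synthesize_labeled_images(st, 4, labeling="conditioning", seed=9)
        path = save_checkpoint(st, tmp_path)
        loaded = load_checkpoint(path)
        again = synthesize_labeled_images(loaded, 4, labeling="conditioning",
                                          seed=9)
        assert np.array_equal(ref.images, again.images)
        assert loaded.history == st.history

    def test_scheduled_checkpoints_written(self, tiny_leaf_data, tmp_path):
        train, _ = tiny_leaf_data
        cfg = _config(total_iterations=4, checkpoint_every=2,
                      checkpoint_dir=str(tmp_path))
        train_wgan_gp_lsr(train, cfg)
        assert (tmp_path / "gan_iter0000002.npz").exists()
        assert (tmp_path / "gan_iter0000004.npz").exists()


def test_nan_loss_aborts_with_diagnostic_record():
    with pytest.raises(GanDivergenceError) as err:
        _check_finite({"critic_loss": float("nan"), "ok": 1.0}, "critic_step")
    assert "critic_loss" in str(err.value)


def test_config_validation():
    with pytest.raises(ValueError):
        _config(batch_size=1)
    with pytest.raises(ValueError):
        _config(learning_rate=0.0)
    with pytest.raises(ValueError):
        _config(lsr=LsrParams(0.22, 5))   # class-count mismatch
    with pytest.raises(ValueError):
        _config(noise_dist="cauchy")
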