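"""Loss functions against hand-computed values and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafgan.losses import (GpParams, LsrParams, cross_entropy,
                            gradient_penalty, lsr_loss,
                            wasserstein_critic_loss,
                            wasserstein_generator_loss)
from leafgan.tensor import Tensor, matmul

rng = np.random.default_rng(7)


def _onehot(i, n):
    q = np.zeros(n)
    q[i] = 1.0
    return q


class TestCrossEntropy:
    def test_matching_onehot_gives_zero(self):
        p = _onehot(2, 5)
        assert cross_entropy(p, _onehot(2, 5)).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_gives_log_n(self):
        for n in (2, 5, 38):
            p = np.full(n, 1.0 / n)
            assert cross_entropy(p, _onehot(0, n)).item() == pytest.approx(np.log(n))

    def test_hand_value_point_eight(self):
        # -ln(0.8) evaluated independently
        p = np.array([0.8, 0.05, 0.05, 0.05, 0.05])
        assert cross_entropy(p, _onehot(0, 5)).item() == pytest.approx(
            0.22314355131420976, abs=1e-12)

    def test_zero_probability_is_floored_not_infinite(self):
        p = np.array([0.0, 1.0])
        v = cross_entropy(p, _onehot(0, 2)).item()
        assert np.isfinite(v) and v > 0

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.2]), _onehot(0, 2))


class TestLsrLoss:
    def test_epsilon_zero_reproduces_cross_entropy(self):
        for _ in range(5):
            p = rng.dirichlet(np.ones(7))
            y = int(rng.integers(7))
            assert lsr_loss(p, y, LsrParams(0.0, 7)).item() == pytest.approx(
                cross_entropy(p, _onehot(y, 7)).item(), abs=1e-12)

    def test_uniform_p_gives_log_n_for_any_epsilon(self):
        n = 38
        p = np.full(n, 1.0 / n)
        for eps in (0.0, 0.22, 0.5, 1.0):
            assert lsr_loss(p, 3, LsrParams(eps, n)).item() == pytest.approx(
                np.log(n), abs=1e-12)

    def test_hand_value_eps_022_n38(self):
        # p(y) = 0.5, remaining mass uniform over the other 37 classes;
        # -(1-eps) ln 0.5 - (eps/38)[ln 0.5 + 37 ln(0.5/37)], evaluated by hand
        n, y = 38, 0
        p = np.full(n, 0.5 / 37)
        p[y] = 0.5
        assert lsr_loss(p, y, LsrParams(0.22, n)).item() == pytest.approx(
            1.4666438071105766, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(eps=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    def test_algebraic_identity_mixture_of_ce_and_uniform_ce(self, eps, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 12))
        p = r.dirichlet(np.ones(n))
        y = int(r.integers(n))
        ce = cross_entropy(p, _onehot(y, n)).item()
        uce = -np.mean(np.log(np.maximum(p, 1e-12)))
        lsr = lsr_loss(p, y, LsrParams(eps, n)).item()
        assert lsr == pytest.approx((1 - eps) * ce + eps * uce, abs=1e-10)

    def test_linear_in_epsilon_for_fixed_p(self):
        p = rng.dirichlet(np.ones(6))
        vals = [lsr_loss(p, 2, LsrParams(e, 6)).item() for e in (0.0, 0.5, 1.0)]
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2, abs=1e-10)


class TestWassersteinLosses:
    def test_hand_arithmetic(self):
        assert wasserstein_critic_loss([1.0, 1.0], [-1.0, -1.0]).item() == -2.0
        assert wasserstein_generator_loss([2.0, 4.0]).item() == -3.0
        assert wasserstein_generator_loss([0.0, 0.0]).item() == 0.0

    def test_equal_scores_give_zero(self):
        s = rng.normal(size=8)
        assert wasserstein_critic_loss(s, s).item() == pytest.approx(0.0)

    def test_translation_invariance_of_critic_loss(self):
        r, f = rng.normal(size=5), rng.normal(size=5)
        base = wasserstein_critic_loss(r, f).item()
        assert wasserstein_critic_loss(r + 17.0, f + 17.0).item() == \
            pytest.approx(base, abs=1e-12)

    def test_generator_loss_homogeneity(self):
        f = rng.normal(size=6)
        assert wasserstein_generator_loss(2 * f).item() == pytest.approx(
            2 * wasserstein_generator_loss(f).item())

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_critic_loss([], [1.0])
        with pytest.raises(ValueError):
            wasserstein_generator_loss([])


class TestGradientPenalty:
    """Closed form for linear critics: penalty = lambda (||w|| - 1)^2."""

    @staticmethod
    def _linear_critic(w):
        wt = Tensor(w, requires_grad=True)
        return lambda x: matmul(x.reshape(x.shape[0], -1), wt)

    def test_unit_norm_critic_gives_zero(self):
        w = np.zeros((8, 1))
        w[0] = 1.0
        pen = gradient_penalty(self._linear_critic(w), rng.normal(size=(4, 8)),
                               rng.normal(size=(4, 8)), GpParams(10.0),
                               np.random.default_rng(0))
        assert pen.item() == pytest.approx(0.0, abs=1e-10)

    def test_norm_three_lambda_ten_gives_forty(self):
        w = np.zeros((8, 1))
        w[1] = 3.0
        pen = gradient_penalty(self._linear_critic(w), rng.normal(size=(4, 8)),
                               rng.normal(size=(4, 8)), GpParams(10.0),
                               np.random.default_rng(0))
        assert pen.item() == pytest.approx(40.0, abs=1e-8)

    def test_closed_form_across_random_linear_critics(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            w = r.normal(size=(6, 1))
            pen = gradient_penalty(self._linear_critic(w),
                                   r.normal(size=(3, 6)), r.normal(size=(3, 6)),
                                   GpParams(10.0), np.random.default_rng(seed))
            expect = 10.0 * (np.linalg.norm(w) - 1.0) ** 2
            assert pen.item() == pytest.approx(expect, abs=1e-6)

    def test_lambda_zero_gives_zero(self):
        w = rng.normal(size=(6, 1))
        pen = gradient_penalty(self._linear_critic(w), rng.normal(size=(3, 6)),
                               rng.normal(size=(3, 6)), GpParams(0.0),
                               np.random.default_rng(0))
        assert pen.item() == 0.0

    def test_shape_mismatch_rejected(self):
        w = rng.normal(size=(6, 1))
        with pytest.raises(ValueError):
            gradient_penalty(self._linear_critic(w), rng.normal(size=(3, 6)),
                             rng.normal(size=(2, 6)), GpParams(10.0),
                             np.random.default_rng(0))


def test_lsr_params_validate_epsilon_range():
    with pytest.raises(ValueError):
        LsrParams(1.2, 5)
    with pytest.raises(ValueError):
        LsrParams(-0.1, 5)
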