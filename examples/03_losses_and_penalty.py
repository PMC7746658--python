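"""The GAN's loss components evaluated on transparent inputs.

Demonstrates: label smoothing interpolates between cross-entropy and the
uniform-target loss; the Wasserstein critic loss is plain score arithmetic;
the gradient penalty has a closed form for linear critics.
"""

import numpy as np

from leafgan import (GpParams, LsrParams, cross_entropy, gradient_penalty,
                     lsr_loss, wasserstein_critic_loss)
from leafgan.tensor import Tensor, matmul

p = np.array([0.8, 0.05, 0.05, 0.05, 0.05])
onehot = np.array([1.0, 0, 0, 0, 0])
print(f"cross-entropy, p(y)=0.8: {cross_entropy(p, onehot).item():.5f}"
      "  (= -ln 0.8)")
for eps in (0.0, 0.22, 1.0):
    print(f"LSR loss, eps={eps:4.2f}: {lsr_loss(p, 0, LsrParams(eps, 5)).item():.5f}")

print("critic loss, real=[1,1] fake=[-1,-1]:",
      wasserstein_critic_loss([1.0, 1.0], [-1.0, -1.0]).item())

w = np.zeros((8, 1))
w[0] = 3.0   # linear critic with gradient norm 3 everywhere
critic = lambda x: matmul(x.reshape(x.shape[0], -1), Tensor(w, requires_grad=True))
rng = np.random.default_rng(0)
pen = gradient_penalty(critic, rng.normal(size=(4, 8)), rng.normal(size=(4, 8)),
                       GpParams(10.0), rng)
print(f"gradient penalty, ||w||=3, lambda=10: {pen.item():.6f}  (= 10*(3-1)^2)")
# eps=0 reproduces cross-entropy exactly; larger eps pulls the loss toward
# the uniform target.  The penalty equals lambda(||grad||-1)^2 because a
# linear critic has the same input gradient at every interpolate.
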