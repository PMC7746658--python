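import numpy as np
import pytest

from leafgan import LeafDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_leaf_data():
    """Two well-separated leaf classes at 16 px (shared across GAN tests)."""
    spec = LeafDatasetSpec(n_classes=2, n_per_class_train=30,
                           n_per_class_test=10, image_size=16,
                           feature_strength=1.0, seed=1)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def leaf_data_32():
    """Two classes at 32 px for classifier-sized smoke runs."""
    spec = LeafDatasetSpec(n_classes=2, n_per_class_train=30,
                           n_per_class_test=30, image_size=32,
                           feature_strength=1.0, seed=1)
    return generate_dataset(spec)


def fd_grad(f, x, eps=1e-6):
    """Central finite differences, the independent oracle for backprop."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
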