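"""Declarative network construction: generator, critic, classifier.

Architectures follow the published full-scale design — a conditional
generator mapping a 1000-d noise×label-embedding vector through a dense
layer and four upsample+conv stages to a 128×128×3 tanh image; a dual-head
critic (unbounded validity score + 38-way class head) with a stride-2 conv
trunk and an asymmetric zero-pad giving the 33×33×32 stage; and a VGG16
classifier with a global average pool before its dense layers.  Every
network scales down for CPU work via ``image_size`` and ``base_channels``,
with the full-scale factories reproducing the published layer tables
row for row (see :func:`shape_walk`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .layers import (Activation, BatchNorm, Conv2D, Dense, Flatten,
                     GlobalAvgPool, MaxPool, Reshape, Sequential, UpSample,
                     ZeroPad)
from .tensor import Tensor, gather_rows, mul, softmax

__all__ = ["NetworkSpec", "LabelEmbedding", "embed_label", "build_generator",
           "build_discriminator", "build_classifier", "shape_walk",
           "full_scale_generator_spec", "full_scale_discriminator_spec",
           "full_scale_classifier_spec", "Generator", "Discriminator",
           "Classifier"]

ROLES = ("generator", "discriminator", "classifier")


class ConfigurationError(ValueError):
    """Raised when a layer plan is incompatible with the requested shapes."""


@dataclass
class NetworkSpec:
    """Declarative description of one network.

    ``base_channels`` is the scaling knob: the full-scale networks use 16
    (generator/critic) and 64 (classifier); tests shrink it.  ``plan`` is
    derived from the role when not given explicitly.
    """

    role: str
    image_size: int
    n_classes: int
    noise_dim: int = 0
    base_channels: int = 16
    plan: Optional[List[dict]] = field(default=None)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.role == "generator":
            if self.image_size % 16:
                raise ConfigurationError(
                    "generator image_size must be a multiple of 16 "
                    "(four upsampling stages from size/16)")
            if self.noise_dim < 1:
                raise ConfigurationError("generator needs noise_dim >= 1")
        if self.role == "classifier" and self.image_size % 32:
            raise ConfigurationError(
                "classifier image_size must be a multiple of 32 "
                "(five max-pooling stages)")
        if self.plan is None:
            self.plan = _default_plan(self)

    def to_dict(self) -> dict:
        return {"role": self.role, "image_size": self.image_size,
                "n_classes": self.n_classes, "noise_dim": self.noise_dim,
                "base_channels": self.base_channels}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


def _default_plan(spec: NetworkSpec) -> List[dict]:
    C = spec.base_channels
    S = spec.image_size
    if spec.role == "generator":
        s0 = S // 16
        plan = [
            {"type": "dense_reshape", "shape": (s0, s0, 8 * C)},
            {"type": "batchnorm"}, {"type": "act", "kind": "relu"},
        ]
        for width in (8 * C, 4 * C, 2 * C):
            plan += [
                {"type": "upsample"},
                {"type": "conv", "filters": width, "stride": 1},
                {"type": "batchnorm"}, {"type": "act", "kind": "relu"},
            ]
        plan += [
            {"type": "upsample"},
            {"type": "conv", "filters": 3, "stride": 1},
            {"type": "act", "kind": "tanh"},
        ]
        return plan
    if spec.role == "discriminator":
        return [
            {"type": "conv", "filters": C, "stride": 2},
            {"type": "act", "kind": "leaky_relu"},
            {"type": "conv", "filters": 2 * C, "stride": 2},
            {"type": "act", "kind": "leaky_relu"},
            {"type": "zeropad", "pad": ((0, 1), (0, 1))},
            {"type": "conv", "filters": 4 * C, "stride": 2},
            {"type": "act", "kind": "leaky_relu"},
            {"type": "conv", "filters": 8 * C, "stride": 1},
            {"type": "act", "kind": "leaky_relu"},
            {"type": "flatten"},
            {"type": "heads", "validity": 1, "classes": spec.n_classes},
        ]
    # classifier: VGG16 layout, 2-2-3-3-3 convs with max pools
    plan = []
    for width, n_convs in ((C, 2), (2 * C, 2), (4 * C, 3), (8 * C, 3), (8 * C, 3)):
        for _ in range(n_convs):
            plan += [{"type": "conv", "filters": width, "stride": 1},
                     {"type": "act", "kind": "relu"}]
        plan.append({"type": "maxpool"})
    plan += [
        {"type": "avgpool"},
        {"type": "dense", "units": 8 * C},
        {"type": "act", "kind": "relu"},
        {"type": "dense", "units": spec.n_classes},
        {"type": "act", "kind": "softmax"},
    ]
    return plan


@dataclass
class LabelEmbedding:
    """Trainable per-class vectors multiplied elementwise with the noise.

    Initialized uniform in [0.5, 1.5] (mean 1, so the conditioned input
    keeps the noise scale while classes start distinct).
    """

    n_classes: int
    noise_dim: int
    seed: int = 0
    table: Tensor = field(default=None, repr=False)

    def __post_init__(self):
        if self.table is None:
            rng = np.random.default_rng(self.seed)
            self.table = Tensor(rng.uniform(0.5, 1.5,
                                            (self.n_classes, self.noise_dim)),
                                requires_grad=True)


def embed_label(label, z, embedding: LabelEmbedding):
    """Condition a noise vector on a class: ``out[i] = z[i] * table[label][i]``.

    Accepts a single label with a 1-D ``z`` or a batch of labels with a 2-D
    ``z``; returns a NumPy array (use the generator forward for the
    differentiable path).
    """
    labels = np.atleast_1d(np.asarray(label, dtype=np.int64))
    if np.any(labels < 0) or np.any(labels >= embedding.n_classes):
        raise ValueError(f"label out of range [0, {embedding.n_classes})")
    z = np.asarray(z, dtype=np.float64)
    rows = embedding.table.data[labels]
    out = np.atleast_2d(z) * rows
    return out[0] if np.isscalar(label) or np.ndim(label) == 0 else out


# -- concrete networks -----------------------------------------------------

def _build_body(spec: NetworkSpec, rng: np.random.Generator,
                in_shape: Tuple[int, ...]) -> Tuple[Sequential, Tuple[int, ...]]:
    layers, shape = [], in_shape
    for k, d in enumerate(spec.plan):
        t = d["type"]
        if t == "dense_reshape":
            units = int(np.prod(d["shape"]))
            layers.append(Dense(int(np.prod(shape)), units, rng))
            layers.append(Reshape(d["shape"]))
            shape = d["shape"]
        elif t == "conv":
            if len(shape) != 3:
                raise ConfigurationError(f"layer {k}: conv on non-image shape {shape}")
            lyr = Conv2D(shape[2], d["filters"], rng, stride=d.get("stride", 1))
            layers.append(lyr)
            shape = lyr.out_shape(shape)
        elif t == "dense":
            layers.append(Dense(int(np.prod(shape)), d["units"], rng))
            shape = (d["units"],)
        elif t == "batchnorm":
            layers.append(BatchNorm(shape[-1]))
        elif t == "act":
            layers.append(Activation(d["kind"]))
        elif t == "upsample":
            layers.append(UpSample(2))
            shape = (shape[0] * 2, shape[1] * 2, shape[2])
        elif t == "maxpool":
            if shape[0] % 2 or shape[1] % 2:
                raise ConfigurationError(f"layer {k}: maxpool on odd size {shape}")
            layers.append(MaxPool())
            shape = (shape[0] // 2, shape[1] // 2, shape[2])
        elif t == "zeropad":
            lyr = ZeroPad(d["pad"])
            layers.append(lyr)
            shape = lyr.out_shape(shape)
        elif t == "avgpool":
            layers.append(GlobalAvgPool())
            shape = (1, 1, shape[2])
        elif t == "flatten":
            layers.append(Flatten())
            shape = (int(np.prod(shape)),)
        elif t == "heads":
            break  # handled by the caller
        else:
            raise ConfigurationError(f"layer {k}: unknown type {t!r}")
    return Sequential(layers), shape


class Generator:
    """Conditional image generator: (z, label) → image in [-1, 1]."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if spec.role != "generator":
            raise ConfigurationError("spec.role must be 'generator'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.embedding = LabelEmbedding(spec.n_classes, spec.noise_dim, seed=seed + 1)
        self.body, out_shape = _build_body(spec, rng, (spec.noise_dim,))
        if out_shape != (spec.image_size, spec.image_size, 3):
            raise ConfigurationError(
                f"generator plan ends at {out_shape}, "
                f"expected {(spec.image_size, spec.image_size, 3)}")

    def params(self):
        return [self.embedding.table] + self.body.params()

    def forward(self, z: np.ndarray, labels: np.ndarray, train: bool = True) -> Tensor:
        labels = np.asarray(labels, dtype=np.int64)
        if np.any(labels < 0) or np.any(labels >= self.spec.n_classes):
            raise ValueError("conditioning label out of range")
        zt = Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        conditioned = mul(zt, gather_rows(self.embedding.table, labels))
        return self.body.forward(conditioned, train=train)

    __call__ = forward

    def state(self) -> dict:
        return {"embedding": self.embedding.table.data, "body": self.body.state()}

    def load_state(self, st: dict) -> None:
        self.embedding.table.data[...] = st["embedding"]
        self.body.load_state(st["body"])


class Discriminator:
    """Dual-head critic: image → (validity score, class logits)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if spec.role != "discriminator":
            raise ConfigurationError("spec.role must be 'discriminator'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        in_shape = (spec.image_size, spec.image_size, 3)
        self.trunk, feat_shape = _build_body(spec, rng, in_shape)
        heads = next(d for d in spec.plan if d["type"] == "heads")
        n_feat = int(np.prod(feat_shape))
        self.validity_head = Dense(n_feat, heads["validity"], rng)
        self.class_head = Dense(n_feat, heads["classes"], rng)

    def params(self):
        return (self.trunk.params() + self.validity_head.params()
                + self.class_head.params())

    def forward(self, images: Tensor, train: bool = True):
        feat = self.trunk.forward(images, train=train)
        validity = self.validity_head.forward(feat)
        logits = self.class_head.forward(feat)
        return validity, logits

    __call__ = forward

    def class_probabilities(self, images: Tensor, train: bool = False) -> Tensor:
        _, logits = self.forward(images, train=train)
        return softmax(logits)

    def state(self) -> dict:
        return {"trunk": self.trunk.state(),
                "validity": self.validity_head.state(),
                "class": self.class_head.state()}

    def load_state(self, st: dict) -> None:
        self.trunk.load_state(st["trunk"])
        self.validity_head.load_state(st["validity"])
        self.class_head.load_state(st["class"])


class Classifier:
    """VGG16-style classifier: image → class probabilities (softmax)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if spec.role != "classifier":
            raise ConfigurationError("spec.role must be 'classifier'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        in_shape = (spec.image_size, spec.image_size, 3)
        self.body, out_shape = _build_body(spec, rng, in_shape)
        if out_shape != (spec.n_classes,):
            raise ConfigurationError(
                f"classifier plan ends at {out_shape}, expected ({spec.n_classes},)")

    def params(self):
        return self.body.params()

    def forward(self, images: Tensor, train: bool = True) -> Tensor:
        return self.body.forward(images, train=train)

    __call__ = forward

    def predict(self, images: np.ndarray, batch_size: int = 100) -> np.ndarray:
        """Argmax class indices (ties → lowest index) without building a graph."""
        from .tensor import no_grad
        out = []
        with no_grad():
            for i in range(0, len(images), batch_size):
                p = self.forward(Tensor(images[i:i + batch_size]), train=False)
                out.append(np.argmax(p.data, axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)

    def state(self) -> dict:
        return {"body": self.body.state()}

    def load_state(self, st: dict) -> None:
        self.body.load_state(st["body"])


def build_generator(spec: NetworkSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed=seed)


def build_discriminator(spec: NetworkSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed=seed)


def build_classifier(spec: NetworkSpec, seed: int = 0) -> Classifier:
    return Classifier(spec, seed=seed)


# -- architecture audit ----------------------------------------------------

def shape_walk(spec: NetworkSpec) -> List[Tuple[str, Tuple[int, ...]]]:
    """Propagate shapes through the layer plan without allocating weights.

    Returns the shape-bearing rows (dense / conv / up-sampling / zero
    padding / pooling / heads) as ``(row label, output shape)`` so the
    full-scale walk can be compared cell by cell against the published
    architecture tables.
    """
    import math

    rows: List[Tuple[str, Tuple[int, ...]]] = []
    if spec.role == "generator":
        shape: Tuple[int, ...] = (spec.noise_dim,)
    else:
        shape = (spec.image_size, spec.image_size, 3)
    for d in spec.plan:
        t = d["type"]
        if t == "dense_reshape":
            shape = d["shape"]
            rows.append(("Dense", shape))
        elif t == "conv":
            stride = d.get("stride", 1)
            if len(shape) != 3:
                raise ConfigurationError(f"conv on non-image shape {shape}")
            shape = (math.ceil(shape[0] / stride), math.ceil(shape[1] / stride),
                     d["filters"])
            label = f"Conv3-{d['filters']}"
            if stride != 1:
                label += f"(stride size = {stride})"
            rows.append((label, shape))
        elif t == "upsample":
            shape = (shape[0] * 2, shape[1] * 2, shape[2])
            rows.append(("Up sampling", shape))
        elif t == "zeropad":
            (pt, pb), (pl, pr) = d["pad"]
            shape = (shape[0] + pt + pb, shape[1] + pl + pr, shape[2])
            rows.append(("Zero padding", shape))
        elif t == "maxpool":
            shape = (shape[0] // 2, shape[1] // 2, shape[2])
            rows.append(("MaxPooling", shape))
        elif t == "avgpool":
            shape = (1, 1, shape[2])
            rows.append(("AverPooling", shape))
        elif t == "dense":
            shape = (d["units"],)
            rows.append(("Dense", shape))
        elif t == "flatten":
            shape = (int(np.prod(shape)),)
        elif t == "heads":
            rows.append(("Dense", (d["validity"],)))
            rows.append(("Dense", (d["classes"],)))
    return rows


# -- full-scale factories (the published architectures) --------------------

def full_scale_generator_spec(n_classes: int = 38) -> NetworkSpec:
    """128×128×3 generator with a 1000-d noise input (published design)."""
    return NetworkSpec("generator", image_size=128, n_classes=n_classes,
                       noise_dim=1000, base_channels=16)


def full_scale_discriminator_spec(n_classes: int = 38) -> NetworkSpec:
    return NetworkSpec("discriminator", image_size=128, n_classes=n_classes,
                       base_channels=16)


def full_scale_classifier_spec(n_classes: int = 38) -> NetworkSpec:
    return NetworkSpec("classifier", image_size=128, n_classes=n_classes,
                       base_channels=64)
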