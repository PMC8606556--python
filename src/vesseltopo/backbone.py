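"""Encoder-decoder pixel classifier with an exposed pre-classifier feature map.

The network is a small U-Net: ``depth`` levels of two 3x3 convolutions and
2x2 max-pooling, a bottleneck, and a mirrored decoder with skip
concatenation.  The top decoder block emits exactly ``hidden_features``
channels, and the final stage is a single 1x1 convolution to ``num_classes``
followed by a per-pixel softmax.  The tensor entering that 1x1 classifier is
the representative feature map handed to the graph stage.

Pure numpy; training uses full-image gradient steps with Adam, a halving
learning-rate schedule and optional flip/rotate augmentation.  All
randomness flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from ._nn import Tensor
from .synth import LabeledImage, NUM_CLASSES


@dataclass(frozen=True)
class BackboneConfig:
    depth: int = 2
    base_channels: int = 8
    hidden_features: int = 16  # channels entering the final 1x1 classifier
    num_classes: int = NUM_CLASSES
    in_channels: int = 3
    learning_rate: float = 2e-5
    lr_halving_interval: int = 10_000
    total_epochs: int = 100
    augment_flip: bool = True
    augment_rotate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_features < 1:
            raise ValueError("hidden_features must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities, shape (P, Q, num_classes)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        s = self.probs.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        if self.probs.min() < -1e-12 or self.probs.max() > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class FeatureMap:
    """Per-pixel backbone features, shape (P, Q, H)."""

    feats: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.feats)):
            raise ValueError("feature map contains non-finite values")


class Backbone:
    """U-Net-style model; parameters live in ``self.params`` (name -> Tensor)."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        c, d = config.base_channels, config.depth

        def add_conv(name: str, k: int, cin: int, cout: int) -> None:
            # He initialization, fan-in mode
            std = np.sqrt(2.0 / (k * k * cin))
            self.params[f"{name}.w"] = Tensor(
                rng.normal(0.0, std, size=(k, k, cin, cout)), requires_grad=True
            )
            self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

        cin = config.in_channels
        for i in range(d):
            cout = c * 2**i
            add_conv(f"enc{i}.conv1", 3, cin, cout)
            add_conv(f"enc{i}.conv2", 3, cout, cout)
            cin = cout
        add_conv("bottleneck.conv1", 3, cin, c * 2**d)
        add_conv("bottleneck.conv2", 3, c * 2**d, c * 2**d)
        cin = c * 2**d
        for i in reversed(range(d)):
            skip = c * 2**i
            out = skip if i > 0 else config.hidden_features
            add_conv(f"dec{i}.reduce", 3, cin, skip)
            add_conv(f"dec{i}.conv", 3, 2 * skip, out)
            cin = out
        add_conv("classifier", 1, config.hidden_features, config.num_classes)

    # -- forward -----------------------------------------------------------

    def _conv(self, name: str, x: Tensor, pad: int) -> Tensor:
        return _nn.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], pad)

    def forward(self, image: np.ndarray) -> tuple[Tensor, Tensor]:
        """Returns (pre-classifier feature tensor, class logits).

        ``image`` is (P, Q, in_channels) with P, Q divisible by 2**depth.
        """
        p, q = image.shape[:2]
        div = 2**self.config.depth
        if p % div or q % div:
            raise ValueError(
                f"image size {p}x{q} not divisible by 2**depth = {div}"
            )
        if image.shape[2] != self.config.in_channels:
            raise ValueError("channel count mismatch")
        x = Tensor(image)
        skips = []
        for i in range(self.config.depth):
            x = _nn.relu(self._conv(f"enc{i}.conv1", x, pad=1))
            x = _nn.relu(self._conv(f"enc{i}.conv2", x, pad=1))
            skips.append(x)
            x = _nn.maxpool2(x)
        x = _nn.relu(self._conv("bottleneck.conv1", x, pad=1))
        x = _nn.relu(self._conv("bottleneck.conv2", x, pad=1))
        for i in reversed(range(self.config.depth)):
            x = _nn.upsample2(x)
            x = _nn.relu(self._conv(f"dec{i}.reduce", x, pad=1))
            x = _nn.concat_channels(skips[i], x)
            x = _nn.relu(self._conv(f"dec{i}.conv", x, pad=1))
        feats = x  # input of the 1x1 classifier
        logits = self._conv("classifier", feats, pad=0)
        return feats, logits

    def parameter_list(self) -> list[Tensor]:
        return list(self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(arrays[k], dtype=_nn.DTYPE).copy()


def build_backbone(config: BackboneConfig) -> Backbone:
    """Construct a backbone with seed-deterministic initialization."""
    return Backbone(config)


def _augment(
    image: np.ndarray, labels: np.ndarray, config: BackboneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if config.augment_flip:
        if rng.random() < 0.5:
            image, labels = image[::-1], labels[::-1]
        if rng.random() < 0.5:
            image, labels = image[:, ::-1], labels[:, ::-1]
    if config.augment_rotate and image.shape[0] == image.shape[1]:
        k = int(rng.integers(0, 4))
        if k:
            image = np.rot90(image, k, axes=(0, 1))
            labels = np.rot90(labels, k, axes=(0, 1))
    return np.ascontiguousarray(image), np.ascontiguousarray(labels)


def train_backbone(
    model: Backbone,
    images: list[LabeledImage],
    config: BackboneConfig | None = None,
    progress: bool = False,
) -> tuple[Backbone, list[dict]]:
    """Train with pixel-wise cross-entropy and Adam; returns loss history.

    One epoch is one pass over the training images (full-image batches).
    The learning rate is ``learning_rate * 0.5 ** (epoch // interval)``.
    """
    if config is None:
        config = model.config
    if not images:
        raise ValueError("need at least one training image")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = _nn.Adam(model.parameter_list(), lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.total_epochs):
        lr = config.learning_rate * 0.5 ** (epoch // config.lr_halving_interval)
        opt.lr = lr
        order = rng.permutation(len(images))
        losses = []
        for idx in order:
            sample = images[idx]
            img, lab = _augment(sample.image, sample.labels, config, rng)
            _, logits = model.forward(img)
            loss, _ = _nn.softmax_cross_entropy(logits, lab)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
        if progress and epoch % 10 == 0:
            print(f"[backbone] epoch {epoch} loss {history[-1]['loss']:.4f}")
    return model, history


def learning_rate_at(config: BackboneConfig, epoch: int) -> float:
    """Scheduled learning rate for a 0-based epoch index."""
    return config.learning_rate * 0.5 ** (epoch // config.lr_halving_interval)


def extract(model: Backbone, image: np.ndarray) -> tuple[FeatureMap, ProbabilityMap]:
    """Deterministic inference: pre-classifier features and class probabilities."""
    feats, logits = model.forward(image)
    probs = _nn.softmax(logits.data)
    return FeatureMap(feats=feats.data.copy()), ProbabilityMap(probs=probs)


def save_backbone(model: Backbone, path) -> None:
    arrays = model.state_arrays()
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_backbone(path) -> Backbone:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        config = BackboneConfig(**json.loads(cfg_json))
        model = Backbone(config)
        model.load_state({k: data[k] for k in data.files if k != "__config__"})
    return model
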