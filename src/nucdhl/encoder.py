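"""The 21-layer convolutional encoder and its supervised training loop.

Architecture
------------
The encoder is a series of "Incept" and "Squeeze" grouped-convolution blocks:

* **Incept block** — an initial 5x5 convolution with stride 2 (the only
  downsampling in the network), followed by parallel left (3x3) and right
  (5x5) convolutions whose outputs are concatenated along channels.
* **Squeeze block** — an initial 1x1 convolution with stride 1, followed by
  parallel left (1x1) and right (3x3) convolutions, concatenated.

Every convolution uses Leaky-ReLU activation and carries an L2 weight
penalty. After the block series comes a final 3x3 convolution, dropout and a
flatten that emits the feature vector consumed by the tree-ensemble head.

The "21 layers" are counted by a fixed audit rule: each convolution sub-layer
counts as one layer, plus the dropout and the flatten. The default
configuration (3 Incept + 3 Squeeze blocks of 3 convolutions each, one final
convolution, dropout, flatten) totals exactly 21; :func:`build_encoder`
re-counts by walking its own graph and refuses any configuration that does
not audit to 21.

Training uses Adam on softmax cross-entropy through a temporary dense
classification head; per-epoch history records loss, accuracy, AUROC, AUPR,
precision and recall for the training and validation splits. Training-split
metrics are accumulated from the training batches themselves (dropout and
augmentation active), the validation split is evaluated clean.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augmentation import AugmentParams, augmented_stream, steps_per_epoch
from .evaluate import compute_metrics
from .exceptions import ConfigurationError, ShapeError, TrainingError

#: Layers the audit counts: convolution sub-layers, dropout, flatten.
AUDITED_LAYERS = (nn.Conv2D, nn.Dropout, nn.Flatten)

REQUIRED_LAYER_COUNT = 21


@dataclass(frozen=True)
class EncoderConfig:
    input_size: int = 64
    incept_blocks: tuple[tuple[int, int], ...] = ((16, 16), (24, 24), (32, 32))
    squeeze_blocks: tuple[tuple[int, int], ...] = ((16, 16), (24, 24), (32, 32))
    initial_filters: int = 16
    final_conv_filters: int = 64
    leaky_slope: float = 0.1
    dropout_rate: float = 0.20
    l2_weight: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.leaky_slope <= 0:
            raise ConfigurationError("leaky_slope must be > 0")

    def counted_layers(self) -> int:
        """Layer count implied by the audit rule (3 convs per block + final
        conv + dropout + flatten)."""
        return 3 * (len(self.incept_blocks) + len(self.squeeze_blocks)) + 3


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 250
    learning_rate: float = 0.00025
    batch_size: int = 32
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    split: float = 0.75
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split < 1.0):
            raise ConfigurationError("split must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.loss != "cross_entropy":
            raise ConfigurationError("only cross_entropy loss is supported")


def desk_train_config(seed: int = 0) -> TrainConfig:
    """Reduced-scale training profile: 25 epochs, other settings unchanged."""
    return TrainConfig(epochs=25, seed=seed)


def audit_layer_count(net: nn.Sequential) -> int:
    """Walk the network graph and count audited layers."""
    return sum(1 for layer in net.walk() if isinstance(layer, AUDITED_LAYERS))


def _conv(cin, cout, kernel, stride, config, rng):
    return [
        nn.Conv2D(cin, cout, kernel, stride=stride, l2=config.l2_weight, rng=rng),
        nn.LeakyReLU(config.leaky_slope),
    ]


def _incept_block(cin, left, right, config, rng):
    init = config.initial_filters
    return [
        *_conv(cin, init, 5, 2, config, rng),
        nn.Parallel(_conv(init, left, 3, 1, config, rng),
                    _conv(init, right, 5, 1, config, rng)),
    ]


def _squeeze_block(cin, left, right, config, rng):
    init = config.initial_filters
    return [
        *_conv(cin, init, 1, 1, config, rng),
        nn.Parallel(_conv(init, left, 1, 1, config, rng),
                    _conv(init, right, 3, 1, config, rng)),
    ]


def build_encoder(config: EncoderConfig | None = None,
                  seed: int = 0) -> nn.Sequential:
    """Build the encoder network and audit its layer count.

    Raises :class:`ConfigurationError` (listing the count) when the audited
    layer total differs from 21.
    """
    if config is None:
        config = EncoderConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEC0DE]))
    layers: list[nn.Layer] = []
    channels = 1
    for left, right in config.incept_blocks:
        layers.extend(_incept_block(channels, left, right, config, rng))
        channels = left + right
    for left, right in config.squeeze_blocks:
        layers.extend(_squeeze_block(channels, left, right, config, rng))
        channels = left + right
    layers.extend(_conv(channels, config.final_conv_filters, 3, 1, config, rng))
    layers.append(nn.Dropout(config.dropout_rate, rng=rng))
    layers.append(nn.Flatten())
    net = nn.Sequential(layers)
    count = audit_layer_count(net)
    if count != REQUIRED_LAYER_COUNT:
        raise ConfigurationError(
            f"encoder audits to {count} layers; the architecture requires "
            f"{REQUIRED_LAYER_COUNT}")
    return net


def feature_length(config: EncoderConfig | None = None) -> int:
    """Flattened feature length for a given configuration."""
    config = config or EncoderConfig()
    size = config.input_size
    for _ in config.incept_blocks:
        size = math.ceil(size / 2)
    return size * size * config.final_conv_filters


@dataclass
class TrainedEncoder:
    """A trained encoder: the feature network, its temporary softmax head,
    the configurations it was trained under, and the per-epoch history."""

    net: nn.Sequential
    head: nn.Dense
    config: EncoderConfig
    tconfig: TrainConfig
    history: pd.DataFrame = field(repr=False)

    def extract_features(self, images: np.ndarray,
                         batch_size: int = 256) -> np.ndarray:
        """Flattened feature vectors (weights frozen, no dropout, no
        augmentation). ``images`` is (N, H, W) at the configured input size."""
        x = _as_input(images, self.config.input_size)
        out = [self.net.forward(x[i:i + batch_size], train=False)
               for i in range(0, len(x), batch_size)]
        features = np.concatenate(out, axis=0)
        if not np.all(np.isfinite(features)):
            raise TrainingError("non-finite features; encoder diverged")
        return features

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """p(cancer) from the network's own softmax head (the conventional
        end-to-end CNN readout)."""
        feats = self.extract_features(images, batch_size)
        return nn.softmax(self.head.forward(feats))[:, 1]

    def run_manifest(self) -> dict:
        return {
            "architecture": asdict(self.config),
            "training": asdict(self.tconfig),
            "counted_layers": audit_layer_count(self.net),
            "feature_length": feature_length(self.config),
            "pretrained_weights": "none",
        }

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        params = self.net.params() + self.head.params()
        np.savez(path / "weights.npz",
                 **{f"p{i}": p.value for i, p in enumerate(params)})
        with open(path / "manifest.json", "w") as fh:
            json.dump(self.run_manifest(), fh, indent=2)
        self.history.to_csv(path / "history.csv", index=False)

    @classmethod
    def load(cls, path) -> "TrainedEncoder":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        arch = manifest["architecture"]
        arch["incept_blocks"] = tuple(map(tuple, arch["incept_blocks"]))
        arch["squeeze_blocks"] = tuple(map(tuple, arch["squeeze_blocks"]))
        config = EncoderConfig(**arch)
        tconfig = TrainConfig(**manifest["training"])
        net = build_encoder(config)
        head = nn.Dense(feature_length(config), 2)
        weights = np.load(path / "weights.npz")
        params = net.params() + head.params()
        for i, p in enumerate(params):
            p.value = weights[f"p{i}"]
            p.grad = np.zeros_like(p.value)
        history = pd.read_csv(path / "history.csv")
        return cls(net=net, head=head, config=config, tconfig=tconfig,
                   history=history)


def _as_input(images: np.ndarray, input_size: int) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[1] != input_size or x.shape[2] != input_size:
        raise ShapeError(
            f"expected (N, {input_size}, {input_size}) images, got {x.shape}")
    return x


def train_encoder(train_data: tuple[np.ndarray, np.ndarray],
                  val_data: tuple[np.ndarray, np.ndarray] | None,
                  tconfig: TrainConfig | None = None,
                  config: EncoderConfig | None = None,
                  augment_params: AugmentParams | None = None,
                  verbose: bool = False) -> TrainedEncoder:
    """Train the encoder end to end through a temporary softmax head.

    ``train_data``/``val_data`` are ``(images, labels)`` with images
    ``(N, H, W)`` in [0, 1] and binary labels (normal = 0, cancer = 1).
    Augmentation, when configured, applies to the training stream only.
    Deterministic per seed up to floating-point reduction order.
    """
    tconfig = tconfig or TrainConfig()
    config = config or EncoderConfig()
    x_train, y_train = train_data
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2:
        raise TrainingError("training data contains a single class")
    x_train = np.asarray(x_train, dtype=np.float32)

    net = build_encoder(config, seed=tconfig.seed)
    head = nn.Dense(feature_length(config), 2, l2=config.l2_weight,
                    rng=np.random.default_rng(
                        np.random.SeedSequence([tconfig.seed, 0x4EAD])))
    params = net.params() + head.params()
    optimizer = nn.Adam(params, lr=tconfig.learning_rate)

    stream = augmented_stream(
        x_train, y_train, params=augment_params, batch=tconfig.batch_size,
        seed=tconfig.seed, augment_samples=augment_params is not None)
    steps = steps_per_epoch(len(x_train), tconfig.batch_size)

    rows = []
    trained = TrainedEncoder(net=net, head=head, config=config,
                             tconfig=tconfig, history=pd.DataFrame())
    for epoch in range(tconfig.epochs):
        losses = []
        batch_probs, batch_labels = [], []
        for _ in range(steps):
            xb, yb = next(stream)
            xb4 = _as_input(xb, config.input_size)
            optimizer.zero_grad()
            feats = net.forward(xb4, train=True)
            logits = head.forward(feats, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            net.backward(head.backward(dlogits))
            optimizer.step()
            losses.append(loss)
            batch_probs.append(nn.softmax(logits)[:, 1])
            batch_labels.append(yb)
        train_rep = compute_metrics(np.concatenate(batch_labels),
                                    np.concatenate(batch_probs), split="train")
        row = {"epoch": epoch, "split": "train",
               "loss": float(np.mean(losses)), **train_rep.as_dict()}
        row.pop("split", None)
        rows.append({"split": "train", **row})
        if val_data is not None:
            xv, yv = val_data
            pv = trained.predict_proba(xv)
            val_loss = -float(np.mean(
                np.log(np.clip(np.where(np.asarray(yv) == 1, pv, 1 - pv),
                               1e-12, None))))
            val_rep = compute_metrics(yv, pv, split="validation")
            vrow = {"epoch": epoch, "loss": val_loss, **val_rep.as_dict()}
            vrow.pop("split", None)
            rows.append({"split": "validation", **vrow})
        if verbose:
            print(f"epoch {epoch + 1}/{tconfig.epochs} "
                  f"loss={np.mean(losses):.4f}")
    trained.history = pd.DataFrame(rows)
    return trained


def extract_features(encoder: TrainedEncoder, images: np.ndarray) -> np.ndarray:
    """Module-level convenience wrapper around
    :meth:`TrainedEncoder.extract_features`."""
    return encoder.extract_features(images)
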