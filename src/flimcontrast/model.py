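"""Encoder and task-classifier heads for maFLIM pixel classification.

The network consumes a preprocessed 900-dimensional pixel (three
zero-padded, calibrated, sum-normalized fluorescence decay channels) and
produces, through a four-layer fully connected encoder with batch
normalization, a 16-unit bottleneck embedding. The contrastive loss is
applied at a fixed structural tap: the fourth encoder layer's output
*after* batch normalization and *before* the ReLU activation. Two
three-layer heads with dropout — margin delineation (lesion vs healthy)
and diagnosis (malignant vs benign-side) — share the activated bottleneck.

Default widths are 900-512-256-128-16 for the encoder and 16-21-14-2 for
each head, which together carry exactly 630,814 trainable parameters
(weights, biases, and batch-norm scale/shift); ``build_default_model``
fails fast if that invariant is ever broken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import DTYPE, Adam, BatchNorm, Dropout, Linear, ReLU

#: Trainable-parameter total pinned by the default architecture.
EXPECTED_DEFAULT_PARAMS = 630_814


@dataclass(frozen=True)
class EncoderConfig:
    input_dim: int = 900
    hidden_widths: tuple[int, int, int] = (512, 256, 128)
    bottleneck: int = 16  # 2 for the visualization variant
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self):
        if len(self.hidden_widths) != 3:
            raise ValueError("encoder has 4 layers: 3 hidden widths + bottleneck")
        if self.bottleneck < 1:
            raise ValueError("bottleneck width must be positive")


@dataclass(frozen=True)
class HeadConfig:
    hidden_widths: tuple[int, int] = (21, 14)
    n_out: int = 2
    dropout: float = 0.5


class Encoder:
    """Four FC layers, each Linear -> BatchNorm -> ReLU.

    ``forward`` returns ``(tap, features)``: the contrastive tap
    (post-batch-norm, pre-activation output of layer 4) and the activated
    features consumed by the heads.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        widths = [config.input_dim, *config.hidden_widths, config.bottleneck]
        self.linears = [Linear(widths[i], widths[i + 1], rng) for i in range(4)]
        self.bns = [
            BatchNorm(widths[i + 1], momentum=config.bn_momentum, eps=config.bn_eps)
            for i in range(4)
        ]
        self.relus = [ReLU() for _ in range(4)]

    def forward(self, x: np.ndarray, training: bool = False,
                batch_stats: bool = False):
        """Forward pass returning ``(tap, features)``.

        ``batch_stats=True`` normalizes by the current batch's statistics
        without updating the running estimates — the convention used for
        silhouette monitoring, where the embedding of interest is the one
        the contrastive loss operates on (meaningful even before the
        running estimates have been warmed up).
        """
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.config.input_dim}), got {x.shape}"
            )
        bn_train = training or batch_stats
        h = x
        for i in range(3):
            h = self.relus[i].forward(self.bns[i].forward(
                self.linears[i].forward(h, training), bn_train, update_stats=training))
        tap = self.bns[3].forward(self.linears[3].forward(h, training),
                                  bn_train, update_stats=training)
        features = self.relus[3].forward(tap)
        return tap, features

    def backward(self, grad_tap: np.ndarray | None = None,
                 grad_features: np.ndarray | None = None) -> None:
        if grad_tap is None and grad_features is None:
            raise ValueError("at least one of grad_tap/grad_features is required")
        g = 0.0
        if grad_features is not None:
            g = self.relus[3].backward(grad_features)
        if grad_tap is not None:
            g = g + grad_tap
        g = self.linears[3].backward(self.bns[3].backward(g))
        for i in (2, 1, 0):
            g = self.relus[i].backward(g)
            g = self.linears[i].backward(self.bns[i].backward(g))

    def params(self):
        out = []
        for lin, bn in zip(self.linears, self.bns):
            out += lin.params() + bn.params()
        return out

    def grads(self):
        out = []
        for lin, bn in zip(self.linears, self.bns):
            out += lin.grads() + bn.grads()
        return out

    def _stateful(self):
        """Arrays defining the module state (params + BN running stats)."""
        out = list(self.params())
        for bn in self.bns:
            out += [bn.running_mean, bn.running_var]
        return out


class Head:
    """Three FC layers with dropout, ending in a 2-node classification layer."""

    def __init__(self, n_in: int, config: HeadConfig, rng: np.random.Generator):
        self.config = config
        w1, w2 = config.hidden_widths
        self.layers = [
            Linear(n_in, w1, rng), Dropout(config.dropout, rng), ReLU(),
            Linear(w1, w2, rng), Dropout(config.dropout, rng), ReLU(),
            Linear(w2, config.n_out, rng),
        ]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class PixelClassifier:
    """Shared encoder plus diagnosis and delineation heads."""

    def __init__(self, encoder_config: EncoderConfig = EncoderConfig(),
                 head_config: HeadConfig = HeadConfig(),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder_config = encoder_config
        self.head_config = head_config
        self.encoder = Encoder(encoder_config, rng)
        self.head_diag = Head(encoder_config.bottleneck, head_config, rng)
        self.head_delin = Head(encoder_config.bottleneck, head_config, rng)

    # -- forward passes -------------------------------------------------
    def embed(self, x, training=False, batch_stats=False):
        """Contrastive-tap embedding (post-BN, pre-ReLU bottleneck)."""
        tap, _ = self.encoder.forward(x, training=training,
                                      batch_stats=batch_stats)
        return tap

    def forward(self, x, training=False):
        tap, features = self.encoder.forward(x, training=training)
        return tap, features, self.head_diag.forward(features, training), \
            self.head_delin.forward(features, training)

    def predict(self, x, batch_size: int = 8192):
        """Evaluation-mode class predictions for both heads."""
        diag, delin = [], []
        for i in range(0, len(x), batch_size):
            _, feats = self.encoder.forward(x[i:i + batch_size], training=False)
            diag.append(np.argmax(self.head_diag.forward(feats), axis=1))
            delin.append(np.argmax(self.head_delin.forward(feats), axis=1))
        return np.concatenate(diag), np.concatenate(delin)

    # -- parameter plumbing ---------------------------------------------
    def params(self):
        return self.encoder.params() + self.head_diag.params() + self.head_delin.params()

    def grads(self):
        return self.encoder.grads() + self.head_diag.grads() + self.head_delin.grads()

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0

    def _stateful(self):
        return (self.encoder._stateful() + self.head_diag.params()
                + self.head_delin.params())

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self._stateful()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for dst, src in zip(self._stateful(), state, strict=True):
            dst[...] = src

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self._stateful())}
        config = json.dumps({
            "encoder": asdict(self.encoder_config),
            "head": asdict(self.head_config),
        })
        np.savez(path, __config__=np.frombuffer(config.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            enc = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in config["encoder"].items()})
            head = HeadConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in config["head"].items()})
            model = cls(enc, head)
            n = len(model._stateful())
            model.set_state([data[f"arr_{i}"] for i in range(n)])
        return model


def count_parameters(model) -> int:
    """Total trainable scalars: weights, biases, batch-norm scale/shift."""
    return int(sum(p.size for p in model.params()))


def build_default_model(seed: int = 0) -> PixelClassifier:
    """Default architecture; fails fast if the parameter total drifts."""
    model = PixelClassifier(EncoderConfig(), HeadConfig(), seed=seed)
    n = count_parameters(model)
    if n != EXPECTED_DEFAULT_PARAMS:
        raise AssertionError(
            f"default architecture has {n} trainable parameters, "
            f"expected {EXPECTED_DEFAULT_PARAMS}"
        )
    return model
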