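"""Multi-exit convolutional classifier.

A VGG-style backbone is organised in macroblocks (one or more 3x3
convolution + ReLU layers followed by a 2x2 max-pool).  An auxiliary
classifier — a flatten-then-linear head — can be attached after any
macroblock's pooling layer; the backbone's own final classifier is a
distinct flatten+linear head on the last block and is always present.

With E heads emitting class-probability vectors f_i(x), the combined
pre-softmax score is

    t = sum_i w_i * f_i(x),        w in R^E trainable,

and the model's final prediction is softmax(t).  Three combination modes
are supported: weighting the post-softmax head probabilities (default),
weighting the raw head logits, or a per-class weight matrix w in R^{E x C}.

The single-head "standard" baseline (no early exits) shares this code
path: its combined score is simply the final head's logits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import losses as L
from .nn import Adam, Conv3x3, Dense, MaxPool2x2, Param, ReLU, softmax, softmax_backward


class ConfigurationError(ValueError):
    """Invalid backbone or exit configuration."""


@dataclass(frozen=True)
class BackboneConfig:
    """Shape of the convolutional backbone.

    Parameters
    ----------
    block_channels:
        Output channel width of each macroblock; the number of macroblocks
        is ``len(block_channels)`` and must be >= 2.
    convs_per_block:
        Number of 3x3 conv+ReLU layers in each macroblock.
    input_size:
        (height, width) of the RGB input; must be divisible by
        ``2 ** len(block_channels)`` because every block halves resolution.
    num_classes:
        Number of output classes C (>= 2).
    """

    block_channels: tuple = (8, 16, 32, 32)
    convs_per_block: tuple = (1, 1, 2, 2)
    input_size: tuple = (16, 16)
    num_classes: int = 2

    def __post_init__(self):
        if len(self.block_channels) < 2:
            raise ConfigurationError("need at least 2 macroblocks")
        if len(self.convs_per_block) != len(self.block_channels):
            raise ConfigurationError("convs_per_block must match block_channels")
        if any(c < 1 for c in self.block_channels) or any(
            k < 1 for k in self.convs_per_block
        ):
            raise ConfigurationError("channel widths and conv counts must be positive")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        h, w = self.input_size
        d = 2 ** len(self.block_channels)
        if h % d or w % d:
            raise ConfigurationError(
                f"input size {h}x{w} not divisible by 2^{len(self.block_channels)}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.block_channels)

    def feature_shape(self, block_idx: int) -> tuple:
        """(channels, height, width) after block ``block_idx``'s pooling."""
        f = 2 ** (block_idx + 1)
        return (
            self.block_channels[block_idx],
            self.input_size[0] // f,
            self.input_size[1] // f,
        )

    def flat_dim(self, block_idx: int) -> int:
        c, h, w = self.feature_shape(block_idx)
        return c * h * w


@dataclass
class ExitOutputs:
    """Per-head and combined outputs for a batch.

    Attributes
    ----------
    per_head_probs:
        (E, N, C) softmax probabilities of each head.
    per_head_logits:
        (E, N, C) raw head scores.
    combined_scores:
        (N, C) pre-softmax combined scores t.
    combined_probs:
        (N, C) softmax(t), the model's final predictive distribution.
    """

    per_head_probs: np.ndarray
    per_head_logits: np.ndarray
    combined_scores: np.ndarray
    combined_probs: np.ndarray

    @property
    def n_heads(self) -> int:
        return self.per_head_probs.shape[0]


def combine_heads(per_head: np.ndarray, w: np.ndarray, per_class: bool = False) -> np.ndarray:
    """Weighted sum of E head output vectors: t = sum_i w_i * f_i.

    ``per_head`` is (E, N, C); ``w`` is (E,) or, with ``per_class``, (E, C).
    """
    per_head = np.asarray(per_head, dtype=float)
    w = np.asarray(w, dtype=float)
    if per_class:
        return np.einsum("enc,ec->nc", per_head, w)
    return np.einsum("enc,e->nc", per_head, w)


class MultiExitModel:
    """Backbone + exit heads + trainable combiner. Built via :func:`build_model`."""

    def __init__(
        self,
        config: BackboneConfig,
        exit_indices: Sequence[int],
        combine_on: str = "probs",
        per_class_weights: bool = False,
        seed: int = 0,
    ):
        if combine_on not in ("probs", "logits"):
            raise ConfigurationError(f"unknown combine mode: {combine_on!r}")
        for idx in exit_indices:
            if not 0 <= idx < config.n_blocks:
                raise ConfigurationError(
                    f"exit index {idx} out of range for {config.n_blocks} blocks"
                )
        self.config = config
        self.exit_indices = list(exit_indices)
        self.combine_on = combine_on
        self.per_class_weights = per_class_weights
        self.is_standard = len(self.exit_indices) == 0
        rng = np.random.default_rng(seed)

        # backbone: per block, [conv, relu] * k then pool
        self.blocks: List[list] = []
        in_ch = 3
        for b in range(config.n_blocks):
            layers = []
            for _ in range(config.convs_per_block[b]):
                layers.append(Conv3x3(in_ch, config.block_channels[b], rng))
                layers.append(ReLU())
                in_ch = config.block_channels[b]
            layers.append(MaxPool2x2())
            self.blocks.append(layers)

        # heads: one per requested exit, plus the backbone's own final head
        C = config.num_classes
        self.head_blocks = self.exit_indices + [config.n_blocks - 1]
        self.heads = [Dense(config.flat_dim(b), C, rng) for b in self.head_blocks]
        self.n_heads = len(self.heads)

        if self.is_standard:
            self.w = Param(np.ones(1))
            self._w_trainable = False
        else:
            if self.n_heads < 2:
                raise ConfigurationError("a multi-exit model needs at least 2 heads")
            shape = (self.n_heads, C) if per_class_weights else (self.n_heads,)
            self.w = Param(np.full(shape, 1.0 / self.n_heads))
            self._w_trainable = True
        self._cache = None

    # ------------------------------------------------------------------ params

    def parameters(self) -> List[Param]:
        ps: List[Param] = []
        for block in self.blocks:
            for layer in block:
                ps.extend(layer.params())
        for head in self.heads:
            ps.extend(head.params())
        if self._w_trainable:
            ps.append(self.w)
        return ps

    def head_param_count(self) -> int:
        """Total head parameters: sum over heads of (flat_dim + 1) * C."""
        return sum(
            (self.config.flat_dim(b) + 1) * self.config.num_classes
            for b in self.head_blocks
        )

    def get_state(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: List[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v

    # ----------------------------------------------------------------- forward

    def _to_nchw(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 4 or batch.shape[3] != 3:
            raise ValueError(f"expected (N, H, W, 3) batch, got {batch.shape}")
        if batch.shape[1:3] != tuple(self.config.input_size):
            raise ValueError(
                f"batch spatial size {batch.shape[1:3]} does not match "
                f"configured input {self.config.input_size}"
            )
        if not np.all(np.isfinite(batch)):
            raise ValueError("batch contains non-finite pixel values")
        return batch.transpose(0, 3, 1, 2)

    def forward_with_exits(self, batch: np.ndarray, train: bool = False) -> ExitOutputs:
        """Run the backbone and all heads on an (N, H, W, 3) batch in [0, 1]."""
        x = self._to_nchw(batch)
        n = x.shape[0]
        feats = []
        for block in self.blocks:
            for layer in block:
                x = layer.forward(x, train=train)
            feats.append(x)

        C = self.config.num_classes
        logits = np.empty((self.n_heads, n, C))
        flats = []
        for i, (head, b) in enumerate(zip(self.heads, self.head_blocks)):
            flat = feats[b].reshape(n, -1)
            flats.append(flat)
            logits[i] = head.forward(flat, train=train)
        probs = softmax(logits, axis=-1)

        if self.is_standard:
            t = logits[0]
        else:
            operand = probs if self.combine_on == "probs" else logits
            t = combine_heads(operand, self.w.value, self.per_class_weights)
        combined = softmax(t, axis=-1)

        out = ExitOutputs(probs, logits, t, combined)
        if train:
            self._cache = out
        return out

    # ---------------------------------------------------------------- backward

    def backward(self, labels: np.ndarray, cfg: L.LossConfig) -> float:
        """Accumulate gradients of the mean multi-exit objective; returns its value.

        Must follow a ``forward_with_exits(..., train=True)`` call.
        """
        out = self._cache
        if out is None:
            raise RuntimeError("backward called without a cached training forward")
        labels = np.asarray(labels, dtype=int)
        n = labels.shape[0]
        rows = np.arange(n)
        probs, logits, t, q = (
            out.per_head_probs,
            out.per_head_logits,
            out.combined_scores,
            out.combined_probs,
        )
        E, C = self.n_heads, self.config.num_classes

        if self.is_standard:
            # combined output IS head 0; objective reduces to (alpha+beta)*l(head0)
            scale = cfg.alpha + cfg.beta
            loss = scale * float(np.mean(L.loss_values(probs[0], labels, cfg)))
            dq = np.zeros((n, C))
            dq[rows, labels] = scale * L.loss_grad_py(probs[0][rows, labels], cfg) / n
            dz = softmax_backward(probs[0], dq)
            dflat = self.heads[0].backward(dz)
            self._backprop_features({self.head_blocks[0]: [dflat]})
            return loss

        loss = L.batch_objective(out, labels, cfg)

        # gradient of the combined-output term through softmax(t)
        dq = np.zeros((n, C))
        dq[rows, labels] = cfg.alpha * L.loss_grad_py(q[rows, labels], cfg) / n
        dt = softmax_backward(q, dq)  # (N, C)

        # combiner-weight gradient
        operand = probs if self.combine_on == "probs" else logits
        if self._w_trainable:
            if self.per_class_weights:
                self.w.grad += np.einsum("nc,enc->ec", dt, operand)
            else:
                self.w.grad += np.einsum("nc,enc->e", dt, operand)

        # per-head gradients: beta-term on own probs, alpha-term through combiner
        wv = self.w.value
        dflat_by_block: dict = {}
        for i in range(E):
            dprob = np.zeros((n, C))
            dprob[rows, labels] = cfg.beta * L.loss_grad_py(probs[i][rows, labels], cfg) / n
            dlogit = np.zeros((n, C))
            # wv[i] is a scalar or, in per-class mode, a length-C vector
            if self.combine_on == "probs":
                dprob = dprob + dt * wv[i]
            else:
                dlogit = dlogit + dt * wv[i]
            dz = softmax_backward(probs[i], dprob) + dlogit
            dflat = self.heads[i].backward(dz)
            dflat_by_block.setdefault(self.head_blocks[i], []).append(dflat)

        self._backprop_features(dflat_by_block)
        return loss

    def _backprop_features(self, dflat_by_block: dict) -> None:
        """Push summed head gradients back through the backbone blocks."""
        dx = None
        for b in range(self.config.n_blocks - 1, -1, -1):
            shape = self.config.feature_shape(b)
            if b in dflat_by_block:
                extra = sum(dflat_by_block[b])
                extra = extra.reshape(-1, *shape)
                dx = extra if dx is None else dx + extra
            if dx is None:
                continue
            for layer in reversed(self.blocks[b]):
                dx = layer.backward(dx)

    # -------------------------------------------------------------- checkpoint

    def metadata(self) -> dict:
        return {
            "block_channels": list(self.config.block_channels),
            "convs_per_block": list(self.config.convs_per_block),
            "input_size": list(self.config.input_size),
            "num_classes": self.config.num_classes,
            "exit_indices": self.exit_indices,
            "combine_on": self.combine_on,
            "per_class_weights": self.per_class_weights,
        }

    def save(self, path) -> None:
        """Self-describing checkpoint: weights as npz + JSON config metadata."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(self.metadata()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MultiExitModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            params = [
                data[f"param_{i}"]
                for i in range(sum(1 for k in data.files if k.startswith("param_")))
            ]
        config = BackboneConfig(
            block_channels=tuple(meta["block_channels"]),
            convs_per_block=tuple(meta["convs_per_block"]),
            input_size=tuple(meta["input_size"]),
            num_classes=meta["num_classes"],
        )
        model = cls(
            config,
            meta["exit_indices"],
            combine_on=meta["combine_on"],
            per_class_weights=meta["per_class_weights"],
        )
        model.set_state(params)
        return model


def vgg16_config(input_size: tuple = (128, 128), num_classes: int = 2) -> BackboneConfig:
    """The full-scale 5-block VGG-16 backbone shape (one exit per pooling layer
    plus the original head gives E = 6)."""
    return BackboneConfig(
        block_channels=(64, 128, 256, 512, 512),
        convs_per_block=(2, 2, 3, 3, 3),
        input_size=input_size,
        num_classes=num_classes,
    )


def build_model(
    config: BackboneConfig,
    exit_indices: Optional[Sequence[int]] = None,
    combine_on: str = "probs",
    per_class_weights: bool = False,
    seed: int = 0,
) -> MultiExitModel:
    """Construct a multi-exit model (or, with no exit indices, the standard baseline).

    ``exit_indices`` lists the macroblocks after whose pooling layer an
    auxiliary flatten+linear head is attached (0-based; duplicates allowed and
    yield independently parameterised heads).  The backbone's own final head
    is always appended, so E = len(exit_indices) + 1.  ``exit_indices=None``
    defaults to one exit per macroblock; ``exit_indices=[]`` builds the
    single-head standard baseline.
    """
    if exit_indices is None:
        exit_indices = list(range(config.n_blocks))
    return MultiExitModel(
        config,
        exit_indices,
        combine_on=combine_on,
        per_class_weights=per_class_weights,
        seed=seed,
    )


def predict(outputs: ExitOutputs):
    """Class index (argmax of combined probs, ties to lowest index) and confidence."""
    probs = np.asarray(outputs.combined_probs, dtype=float)
    classes = np.argmax(probs, axis=-1)
    confidences = probs[np.arange(probs.shape[0]), classes]
    return classes, confidences
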