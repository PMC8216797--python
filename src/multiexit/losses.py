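"""Per-sample classification losses and the multi-exit training objective.

The objective for one sample is

    l~(y, x) = alpha * l(y, combined output) + beta * sum_i l(y, exit_i output)

where the sum runs over every attached head (early exits plus the backbone's
own final classifier) and ``l`` is either the cross-entropy or the focal loss

    l_focal(y, p) = -(1 - p_y)^gamma * log(p_y),

which reduces to the cross-entropy at gamma = 0 and down-weights samples the
model is already confident about (gamma > 0), acting as an entropy-raising
regularizer that improves calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: floor applied to probabilities inside logarithms, so a saturated softmax
#: never produces an infinite loss
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Configuration for the multi-exit objective.

    Parameters
    ----------
    loss_kind:
        ``"cross_entropy"`` or ``"focal"``.
    gamma:
        Focal-loss focusing parameter (>= 0); ignored for cross-entropy.
    alpha:
        Weight of the combined-output loss term (>= 0).
    beta:
        Weight of the summed per-exit loss terms (>= 0).
    """

    loss_kind: str = "cross_entropy"
    gamma: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.loss_kind not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss kind: {self.loss_kind!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


def _check_label(label: int, n_classes: int) -> int:
    label = int(label)
    if not 0 <= label < n_classes:
        raise ValueError(f"label {label} out of range for C={n_classes}")
    return label


def cross_entropy_loss(probs: np.ndarray, label: int) -> float:
    """-log p_y for a single probability vector."""
    probs = np.asarray(probs, dtype=float)
    label = _check_label(label, probs.shape[-1])
    return float(-np.log(max(probs[label], PROB_FLOOR)))


def focal_loss(probs: np.ndarray, label: int, gamma: float) -> float:
    """-(1 - p_y)^gamma * log p_y; gamma = 0 recovers the cross-entropy."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    probs = np.asarray(probs, dtype=float)
    label = _check_label(label, probs.shape[-1])
    p = max(probs[label], PROB_FLOOR)
    return float(-((1.0 - probs[label]) ** gamma) * np.log(p))


def loss_values(probs: np.ndarray, labels: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Vectorized per-sample loss over a (N, C) probability array."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p_y = probs[np.arange(len(labels)), labels]
    log_p = np.log(np.maximum(p_y, PROB_FLOOR))
    if cfg.loss_kind == "focal":
        return -((1.0 - p_y) ** cfg.gamma) * log_p
    return -log_p


def loss_grad_py(p_y: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """d(loss)/d(p_y), the derivative with respect to the true-class probability.

    Cross-entropy: -1/p_y.  Focal:
    gamma (1-p_y)^(gamma-1) log p_y - (1-p_y)^gamma / p_y.
    """
    p = np.maximum(np.asarray(p_y, dtype=float), PROB_FLOOR)
    if cfg.loss_kind != "focal" or cfg.gamma == 0:
        return -1.0 / p
    one_minus = np.maximum(1.0 - p, 0.0)
    # (1-p)^(gamma-1) diverges at p=1 for gamma < 1; floor keeps it finite
    base = np.maximum(one_minus, PROB_FLOOR) if cfg.gamma < 1 else one_minus
    return cfg.gamma * base ** (cfg.gamma - 1.0) * np.log(p) - one_minus ** cfg.gamma / p


def _single_loss(probs: np.ndarray, label: int, cfg: LossConfig) -> float:
    if cfg.loss_kind == "focal":
        return focal_loss(probs, label, cfg.gamma)
    return cross_entropy_loss(probs, label)


def multiexit_loss(outputs, label: int, cfg: LossConfig) -> float:
    """Objective for one sample: alpha * l(combined) + beta * sum_i l(exit_i).

    ``outputs`` is an :class:`~multiexit.model.ExitOutputs` holding a single
    sample (or 1-sample batch); the beta-sum runs over all heads, including
    the backbone's original classifier, but not the combined output itself.
    """
    per_head = np.asarray(outputs.per_head_probs, dtype=float)
    combined = np.asarray(outputs.combined_probs, dtype=float)
    if combined.ndim == 2:
        if combined.shape[0] != 1:
            raise ValueError("multiexit_loss expects a single sample")
        combined = combined[0]
        per_head = per_head[:, 0, :]
    total = cfg.alpha * _single_loss(combined, label, cfg)
    for head_probs in per_head:
        total += cfg.beta * _single_loss(head_probs, label, cfg)
    return float(total)


def batch_objective(outputs, labels, cfg: LossConfig) -> float:
    """Mean multi-exit loss over a batch (the empirical-risk minibatch term)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty batch")
    combined = np.asarray(outputs.combined_probs, dtype=float)
    per_head = np.asarray(outputs.per_head_probs, dtype=float)
    if combined.shape[0] != labels.shape[0]:
        raise ValueError("batch length mismatch between outputs and labels")
    total = cfg.alpha * loss_values(combined, labels, cfg)
    for i in range(per_head.shape[0]):
        total = total + cfg.beta * loss_values(per_head[i], labels, cfg)
    return float(np.mean(total))
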