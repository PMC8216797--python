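"""Post-hoc calibration and calibration metrics.

A classifier is calibrated when, among samples predicted with confidence p,
a fraction p is actually correct.  This module provides:

* temperature scaling — replacing softmax(t) by softmax(t / T) with a scalar
  T > 0 fitted on validation negative log-likelihood; order-preserving,
  hence accuracy-neutral;
* equal-width confidence binning, per-bin accuracy/confidence, and the
  expected calibration error (ECE), the bin-weighted mean absolute gap
  between accuracy and confidence;
* data for reliability diagrams and confidence histograms;
* per-exit diagnostic reports for multi-exit models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .losses import PROB_FLOOR
from .nn import softmax

#: search interval for the fitted temperature
T_BOUNDS = (0.05, 10.0)


@dataclass
class PredictionTable:
    """Per-sample confidences, predictions and true labels (plus raw scores)."""

    confidence: np.ndarray
    predicted: np.ndarray
    true: np.ndarray
    scores: Optional[np.ndarray] = None  # (N, C) pre-softmax combined scores

    def __post_init__(self):
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=int)
        self.true = np.asarray(self.true, dtype=int)
        n = len(self.confidence)
        if len(self.predicted) != n or len(self.true) != n:
            raise ValueError("column lengths differ")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValueError("confidences must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.confidence)

    @property
    def correct(self) -> np.ndarray:
        return self.predicted == self.true

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "sample_id": np.arange(len(self)),
                "confidence": self.confidence,
                "predicted": self.predicted,
                "true": self.true,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionTable":
        df = pd.read_csv(path)
        return cls(
            df["confidence"].to_numpy(),
            df["predicted"].to_numpy(),
            df["true"].to_numpy(),
        )


@dataclass
class CalibrationBins:
    """Equal-width partition of (0, 1] into M bins with per-bin statistics.

    Bin m (1-based) covers ((m-1)/M, m/M]; zero confidence falls in bin 1.
    ``acc`` and ``conf`` are NaN for empty bins and excluded downstream.
    """

    M: int
    counts: np.ndarray  # (M,) int
    acc: np.ndarray  # (M,) float, NaN when empty
    conf: np.ndarray  # (M,) float, NaN when empty

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def edges(self) -> np.ndarray:
        return np.arange(1, self.M + 1) / self.M

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.M) + 0.5) / self.M


def temperature_scale(scores: np.ndarray, T: float) -> np.ndarray:
    """softmax(scores / T); T > 0.  Argmax (hence accuracy) is unchanged."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return softmax(scores / T, axis=-1)


def nll_at_temperature(scores: np.ndarray, labels: np.ndarray, T: float) -> float:
    """Mean cross-entropy of temperature-scaled scores against labels."""
    probs = temperature_scale(scores, T)
    p_y = probs[np.arange(len(labels)), np.asarray(labels, dtype=int)]
    return float(-np.mean(np.log(np.maximum(p_y, PROB_FLOOR))))


def fit_temperature(scores: np.ndarray, labels: np.ndarray) -> float:
    """Fit T by minimizing validation NLL over a bounded interval.

    Scalar bounded minimization on [0.05, 10] to tolerance 1e-4; guaranteed
    not to be worse than T = 1 (falls back to 1 otherwise).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0 or len(labels) == 0:
        raise ValueError("empty validation set")
    res = minimize_scalar(
        lambda T: nll_at_temperature(scores, labels, T),
        bounds=T_BOUNDS,
        method="bounded",
        options={"xatol": 1e-4},
    )
    T = float(res.x)
    if nll_at_temperature(scores, labels, T) > nll_at_temperature(scores, labels, 1.0) + 1e-8:
        return 1.0
    return T


def bin_predictions(table: PredictionTable, M: int) -> CalibrationBins:
    """Assign samples to M equal-width confidence bins and compute per-bin stats."""
    if M < 1:
        raise ValueError("M must be >= 1")
    edges = np.arange(1, M + 1) / M
    # first edge >= confidence; p in ((m-1)/M, m/M] -> bin m, p = 0 -> bin 1
    bin_idx = np.searchsorted(edges, table.confidence, side="left")
    bin_idx = np.minimum(bin_idx, M - 1)
    counts = np.bincount(bin_idx, minlength=M)
    acc = np.full(M, np.nan)
    conf = np.full(M, np.nan)
    correct = table.correct.astype(float)
    for m in range(M):
        if counts[m] > 0:
            sel = bin_idx == m
            acc[m] = correct[sel].mean()
            conf[m] = table.confidence[sel].mean()
    return CalibrationBins(M=M, counts=counts, acc=acc, conf=conf)


def expected_calibration_error(bins: CalibrationBins, N: int) -> float:
    """ECE = sum_m (B_m / N) |acc(B_m) - conf(B_m)| over nonempty bins."""
    if N <= 0:
        raise ValueError("N must be positive")
    nonempty = bins.counts > 0
    gaps = np.abs(bins.acc[nonempty] - bins.conf[nonempty])
    return float(np.sum(bins.counts[nonempty] / N * gaps))


def ece(table: PredictionTable, M: int = 10) -> float:
    """Convenience: bin a prediction table and return its ECE."""
    return expected_calibration_error(bin_predictions(table, M), len(table))


def reliability_diagram_data(bins: CalibrationBins) -> pd.DataFrame:
    """One row per nonempty bin: midpoint, conf, acc, gap = conf - acc."""
    nonempty = bins.counts > 0
    return pd.DataFrame(
        {
            "bin": np.arange(1, bins.M + 1)[nonempty],
            "midpoint": bins.midpoints[nonempty],
            "count": bins.counts[nonempty],
            "conf": bins.conf[nonempty],
            "acc": bins.acc[nonempty],
            "gap": (bins.conf - bins.acc)[nonempty],
        }
    )


def confidence_histogram_data(table: PredictionTable, M: int = 10) -> dict:
    """Histogram of confidences plus overall average accuracy and confidence."""
    if len(table) == 0:
        raise ValueError("empty prediction table")
    bins = bin_predictions(table, M)
    return {
        "counts": bins.counts,
        "midpoints": bins.midpoints,
        "avg_accuracy": float(table.correct.mean()),
        "avg_confidence": float(table.confidence.mean()),
    }


def per_exit_report(
    outputs,
    labels: np.ndarray,
    apply_ts: bool = False,
    val_outputs=None,
    val_labels: Optional[np.ndarray] = None,
    M: int = 10,
    global_ts: bool = False,
) -> pd.DataFrame:
    """Accuracy and ECE of every head's output taken in isolation.

    With ``apply_ts``, a temperature is fitted per head on the validation
    log-probabilities before evaluation (or one shared temperature fitted on
    the combined validation scores when ``global_ts``).  Per-head accuracy is
    unaffected by its own temperature.
    """
    labels = np.asarray(labels, dtype=int)
    E = outputs.n_heads
    if outputs.per_head_probs.shape[1] != len(labels):
        raise ValueError("outputs/labels length mismatch")
    if apply_ts and (val_outputs is None or val_labels is None):
        raise ValueError("validation outputs required when applying TS")

    shared_T = None
    if apply_ts and global_ts:
        shared_T = fit_temperature(val_outputs.combined_scores, val_labels)

    rows: List[dict] = []
    for i in range(E):
        scores = np.log(np.maximum(outputs.per_head_probs[i], PROB_FLOOR))
        T = 1.0
        if apply_ts:
            if global_ts:
                T = shared_T
            else:
                val_scores = np.log(
                    np.maximum(val_outputs.per_head_probs[i], PROB_FLOOR)
                )
                T = fit_temperature(val_scores, np.asarray(val_labels, dtype=int))
        probs = temperature_scale(scores, T)
        pred = np.argmax(probs, axis=-1)
        confi = probs[np.arange(len(labels)), pred]
        table = PredictionTable(confi, pred, labels)
        rows.append(
            {
                "exit": i + 1,
                "accuracy": float(table.correct.mean()),
                "ece": ece(table, M),
                "temperature": T,
            }
        )
    return pd.DataFrame(rows)
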