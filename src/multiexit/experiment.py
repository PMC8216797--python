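"""Training loop, evaluation, the 8-variant experiment grid, and reports.

The grid crosses architecture (standard single-head baseline vs multi-exit),
training loss (cross-entropy vs focal) and post-hoc temperature scaling
(off/on) — eight variants.  Temperature scaling is post-training, so each
(architecture, loss) pair is trained once per run and evaluated twice; the
TS row of a pair therefore has bit-identical accuracy to the non-TS row.
Every experiment is averaged over independent runs whose seeds are derived
from the master seed as ``master + run_index``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import calibration as cal
from .data import SynthParams, generate_synthetic_dataset, prepare_splits, to_arrays
from .losses import LossConfig
from .model import BackboneConfig, MultiExitModel, build_model, predict
from .nn import Adam

logger = logging.getLogger("multiexit")

EVAL_CHUNK = 512


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam throughout)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    n_runs: int = 5
    seed: int = 0
    early_stopping_patience: int = 10

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.n_runs < 1 or self.early_stopping_patience < 0:
            raise ValueError("invalid n_runs or patience")


@dataclass(frozen=True)
class VariantSpec:
    architecture: str  # "standard" | "multiexit"
    loss: str  # "cross_entropy" | "focal"
    ts: bool

    def __post_init__(self):
        if self.architecture not in ("standard", "multiexit"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def name(self) -> str:
        return f"{self.architecture}_{self.loss}_{'ts' if self.ts else 'nots'}"


ALL_VARIANTS: Tuple[VariantSpec, ...] = tuple(
    VariantSpec(a, l, t)
    for a in ("standard", "multiexit")
    for l in ("cross_entropy", "focal")
    for t in (False, True)
)


@dataclass
class ExperimentReport:
    """Per-run and aggregated accuracy/ECE for each variant, plus diagnostics."""

    per_run: pd.DataFrame  # run, architecture, loss, ts, accuracy, ece, temperature
    curves: pd.DataFrame  # run, architecture, loss, epoch, train_loss, val_loss
    tables: Dict[str, cal.PredictionTable] = field(default_factory=dict)
    per_exit: Optional[pd.DataFrame] = None

    @property
    def summary(self) -> pd.DataFrame:
        g = self.per_run.groupby(["architecture", "loss", "ts"], sort=False)
        out = g.agg(
            acc_mean=("accuracy", "mean"),
            acc_sd=("accuracy", "std"),
            ece_mean=("ece", "mean"),
            ece_sd=("ece", "std"),
        ).reset_index()
        return out.fillna({"acc_sd": 0.0, "ece_sd": 0.0})


def _forward_chunked(model: MultiExitModel, X: np.ndarray):
    """Memory-bounded forward over a large evaluation set."""
    outs = [
        model.forward_with_exits(X[i : i + EVAL_CHUNK])
        for i in range(0, len(X), EVAL_CHUNK)
    ]
    from .model import ExitOutputs

    return ExitOutputs(
        np.concatenate([o.per_head_probs for o in outs], axis=1),
        np.concatenate([o.per_head_logits for o in outs], axis=1),
        np.concatenate([o.combined_scores for o in outs], axis=0),
        np.concatenate([o.combined_probs for o in outs], axis=0),
    )


def train_model(
    model: MultiExitModel,
    train: Tuple[np.ndarray, np.ndarray],
    val: Tuple[np.ndarray, np.ndarray],
    loss_cfg: LossConfig,
    cfg: TrainConfig,
) -> Dict[str, list]:
    """Adam minibatch training with early stopping on the validation objective.

    Restores the best-validation parameters before returning.  Returns the
    per-epoch history (train objective over minibatches, validation
    objective).  Raises on divergence (non-finite loss).
    """
    X, y = train
    Xv, yv = val
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("train and validation splits must be nonempty")
    rng = np.random.default_rng(cfg.seed + 10_000)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state = model.get_state()
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(X))
        epoch_losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            model.forward_with_exits(X[idx], train=True)
            loss = model.backward(y[idx], loss_cfg)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: loss={loss} at epoch {epoch}")
            opt.step()
            epoch_losses.append(loss)
        from .losses import batch_objective

        val_out = _forward_chunked(model, Xv)
        val_loss = batch_objective(val_out, yv, loss_cfg)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        logger.debug(
            "epoch %d train %.4f val %.4f (%.2fs)",
            epoch,
            history["train_loss"][-1],
            val_loss,
            time.perf_counter() - t0,
        )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.early_stopping_patience:
                break
    model.set_state(best_state)
    return history


def evaluate(
    model: MultiExitModel,
    split: Tuple[np.ndarray, np.ndarray],
    M: int = 10,
    ts: bool = False,
    val: Optional[Tuple[np.ndarray, np.ndarray]] = None,
):
    """Accuracy and ECE of the combined output on a split.

    With ``ts``, a temperature is fitted on the validation combined scores and
    applied to the test scores before confidences are read off; the argmax
    (hence accuracy) is unchanged by construction.  Returns
    (accuracy, ece, PredictionTable, temperature).
    """
    X, y = split
    if len(X) == 0:
        raise ValueError("empty evaluation split")
    out = _forward_chunked(model, X)
    T = 1.0
    if ts:
        if val is None:
            raise ValueError("temperature scaling requires a validation split")
        val_out = _forward_chunked(model, val[0])
        T = cal.fit_temperature(val_out.combined_scores, val[1])
    probs = cal.temperature_scale(out.combined_scores, T)
    pred = np.argmax(probs, axis=-1)
    conf = probs[np.arange(len(y)), pred]
    table = cal.PredictionTable(conf, pred, np.asarray(y, dtype=int), scores=out.combined_scores)
    accuracy = float(np.mean(pred == y))
    ece_val = cal.ece(table, M)
    return accuracy, ece_val, table, T


def _variant_model(
    architecture: str, backbone: BackboneConfig, seed: int
) -> MultiExitModel:
    exits = [] if architecture == "standard" else list(range(backbone.n_blocks))
    return build_model(backbone, exits, seed=seed)


def _variant_loss(loss: str, architecture: str, gamma: float) -> LossConfig:
    beta = 0.0 if architecture == "standard" else 1.0
    return LossConfig(loss_kind=loss, gamma=gamma, alpha=1.0, beta=beta)


def run_grid(
    synth_params: SynthParams,
    backbone: BackboneConfig,
    train_cfg: TrainConfig,
    variants: Sequence[VariantSpec] = ALL_VARIANTS,
    gamma: float = 2.0,
    M: int = 10,
    fixed_split: bool = False,
    collect_per_exit: bool = True,
) -> ExperimentReport:
    """Run the experiment grid on the synthetic task, averaged over runs.

    Per run: generate data, patient-split and preprocess, train each needed
    (architecture, loss) pair once, evaluate with and without temperature
    scaling.  Run r derives all its seeds from ``train_cfg.seed + r`` (data,
    split, initialisation and shuffling); ``fixed_split`` reuses run 0's
    data and split in every run so only training randomness varies.
    """
    if not variants:
        raise ValueError("need at least one variant")
    pairs = sorted({(v.architecture, v.loss) for v in variants})
    rows, curve_rows, per_exit_rows = [], [], []
    tables: Dict[str, cal.PredictionTable] = {}
    for run in range(train_cfg.n_runs):
        run_seed = train_cfg.seed + run
        data_seed = train_cfg.seed if fixed_split else run_seed
        images = generate_synthetic_dataset(replace(synth_params, seed=data_seed))
        splits = prepare_splits(images, seed=data_seed)
        train = to_arrays(splits["train"])
        val = to_arrays(splits["val"])
        test = to_arrays(splits["test"])
        for arch, loss in pairs:
            t0 = time.perf_counter()
            model = _variant_model(arch, backbone, seed=run_seed)
            loss_cfg = _variant_loss(loss, arch, gamma)
            cfg = replace(train_cfg, seed=run_seed)
            history = train_model(model, train, val, loss_cfg, cfg)
            for ts in (False, True):
                if VariantSpec(arch, loss, ts) not in variants:
                    continue
                acc, ece_val, table, T = evaluate(model, test, M=M, ts=ts, val=val)
                rows.append(
                    {
                        "run": run,
                        "architecture": arch,
                        "loss": loss,
                        "ts": ts,
                        "accuracy": acc,
                        "ece": ece_val,
                        "temperature": T,
                    }
                )
                tables[VariantSpec(arch, loss, ts).name] = table
            for epoch, (tl, vl) in enumerate(
                zip(history["train_loss"], history["val_loss"])
            ):
                curve_rows.append(
                    {
                        "run": run,
                        "architecture": arch,
                        "loss": loss,
                        "epoch": epoch,
                        "train_loss": tl,
                        "val_loss": vl,
                    }
                )
            if collect_per_exit and arch == "multiexit":
                test_out = _forward_chunked(model, test[0])
                val_out = _forward_chunked(model, val[0])
                for apply_ts in (False, True):
                    rep = cal.per_exit_report(
                        test_out,
                        test[1],
                        apply_ts=apply_ts,
                        val_outputs=val_out,
                        val_labels=val[1],
                        M=M,
                    )
                    rep.insert(0, "run", run)
                    rep.insert(1, "loss", loss)
                    rep.insert(2, "ts", apply_ts)
                    per_exit_rows.append(rep)
            logger.info(
                "run %d %s/%s: %.1fs, %d epochs",
                run,
                arch,
                loss,
                time.perf_counter() - t0,
                len(history["train_loss"]),
            )
    report = ExperimentReport(
        per_run=pd.DataFrame(rows),
        curves=pd.DataFrame(curve_rows),
        tables=tables,
        per_exit=pd.concat(per_exit_rows, ignore_index=True) if per_exit_rows else None,
    )
    return report


def make_report(report: ExperimentReport, out_dir) -> List[Path]:
    """Write the results table and all diagram data as CSV files."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc
    written: List[Path] = []

    path = out_dir / "results.csv"
    report.summary.to_csv(path, index=False)
    written.append(path)

    path = out_dir / "per_run.csv"
    report.per_run.to_csv(path, index=False)
    written.append(path)

    path = out_dir / "loss_curves.csv"
    report.curves.to_csv(path, index=False)
    written.append(path)

    for name, table in report.tables.items():
        bins = cal.bin_predictions(table, 10)
        path = out_dir / f"reliability_{name}.csv"
        cal.reliability_diagram_data(bins).to_csv(path, index=False)
        written.append(path)
        hist = cal.confidence_histogram_data(table, 10)
        path = out_dir / f"confhist_{name}.csv"
        pd.DataFrame(
            {
                "midpoint": hist["midpoints"],
                "count": hist["counts"],
                "avg_accuracy": hist["avg_accuracy"],
                "avg_confidence": hist["avg_confidence"],
            }
        ).to_csv(path, index=False)
        written.append(path)
        path = out_dir / f"predictions_{name}.csv"
        table.to_csv(path)
        written.append(path)

    if report.per_exit is not None:
        path = out_dir / "per_exit.csv"
        report.per_exit.to_csv(path, index=False)
        written.append(path)
    return written
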