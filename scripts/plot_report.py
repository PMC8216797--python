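#!/usr/bin/env python
"""Render reliability diagrams and confidence histograms from a report directory.

Optional companion to `multiexit grid` / `make_report`, which emit all diagram
data as CSV; this script only draws.

Usage:  python scripts/plot_report.py REPORT_DIR [--out FIG_DIR]
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_reliability(csv_path: Path, out: Path) -> None:
    df = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(4, 4))
    width = 0.08
    ax.bar(df["midpoint"], df["acc"], width=width, color="tab:blue", label="accuracy")
    ax.bar(
        df["midpoint"], df["gap"], width=width, bottom=df["acc"],
        color="tab:red", alpha=0.6, label="gap (conf - acc)",
    )
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("confidence")
    ax.set_ylabel("accuracy")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(csv_path.stem.replace("reliability_", ""), fontsize=9)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def plot_confhist(csv_path: Path, out: Path) -> None:
    df = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(4, 3))
    frac = df["count"] / df["count"].sum()
    ax.bar(df["midpoint"], frac, width=0.08, color="tab:blue")
    ax.axvline(df["avg_accuracy"].iloc[0], color="gold", ls="--", label="avg accuracy")
    ax.axvline(df["avg_confidence"].iloc[0], color="tab:red", ls="--", label="avg confidence")
    ax.set_xlabel("confidence")
    ax.set_ylabel("fraction of samples")
    ax.legend(fontsize=8)
    ax.set_title(csv_path.stem.replace("confhist_", ""), fontsize=9)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def plot_loss_curves(csv_path: Path, out: Path) -> None:
    df = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (arch, loss), g in df.groupby(["architecture", "loss"]):
        mean = g.groupby("epoch")["train_loss"].mean()
        ax.plot(mean.index, mean.values, label=f"{arch}/{loss}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("training loss")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("report_dir", type=Path)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()
    out_dir = args.out or args.report_dir / "figures"
    out_dir.mkdir(parents=True, exist_ok=True)
    for csv_path in sorted(args.report_dir.glob("reliability_*.csv")):
        plot_reliability(csv_path, out_dir / f"{csv_path.stem}.png")
    for csv_path in sorted(args.report_dir.glob("confhist_*.csv")):
        plot_confhist(csv_path, out_dir / f"{csv_path.stem}.png")
    curves = args.report_dir / "loss_curves.csv"
    if curves.exists():
        plot_loss_curves(curves, out_dir / "loss_curves.png")
    print(f"figures written to {out_dir}")


if __name__ == "__main__":
    main()
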