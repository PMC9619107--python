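"""Line charts for the study pipeline (estimate vs df(g); discrepancy vs C/R)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_estimates_by_df", "plot_diff_by_bins"]


def plot_estimates_by_df(item_table: pd.DataFrame, path: str | Path) -> None:
    """Mean rit/eta1/eta2 against the item's degrees of freedom."""
    means = (
        item_table.dropna(subset=["rit"])
        .groupby("df_g")[["rit", "eta1", "eta2"]]
        .mean()
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    for col, marker in (("rit", "s"), ("eta1", "^"), ("eta2", "o")):
        ax.plot(means.index, means[col], marker=marker, label=col)
    ax.set_xlabel("df(g) = item categories − 1")
    ax.set_ylabel("mean estimate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diff_by_bins(summary: pd.DataFrame, path: str | Path,
                      xlabel: str = "bin") -> None:
    """Mean eta2 − eta1 per bin, with the overall row dropped."""
    body = summary[summary["bin"].astype(str) != "overall"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(len(body)), body["mean"], marker="o")
    ax.set_xticks(range(len(body)))
    ax.set_xticklabels([str(b) for b in body["bin"]], rotation=45, ha="right")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean eta2 − eta1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
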