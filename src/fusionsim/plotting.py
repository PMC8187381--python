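"""Plots for sweep tables and run trajectories (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_coop_vs_fusion", "plot_metric_sweep", "plot_trajectory"]


def _seed_means(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return (table.groupby(by, as_index=False)[["avg_cooperation",
                                               "avg_fusion"]].mean())


def plot_coop_vs_fusion(table: pd.DataFrame, out: str | Path,
                        label_col: str = "s_policy") -> Path:
    """Scatter of seed-averaged cooperation against fusion, one marker per
    condition, colour-grouped by ostracism type."""
    fig, ax = plt.subplots(figsize=(5, 4))
    means = _seed_means(table, ["ostracism_type", label_col])
    for t, sub in means.groupby("ostracism_type"):
        ax.scatter(sub["avg_fusion"], sub["avg_cooperation"],
                   label=f"type-{t}")
        for _, row in sub.iterrows():
            ax.annotate(str(row[label_col]),
                        (row["avg_fusion"], row["avg_cooperation"]),
                        fontsize=7, alpha=0.7)
    ax.set_xlabel("average fusion")
    ax.set_ylabel("average cooperation")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_metric_sweep(table: pd.DataFrame, x: str, out: str | Path) -> Path:
    """Seed-averaged cooperation and fusion as functions of one swept
    parameter, one line per ostracism type."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    means = _seed_means(table, ["ostracism_type", x])
    for metric, ax in zip(("avg_cooperation", "avg_fusion"), axes):
        for t, sub in means.groupby("ostracism_type"):
            sub = sub.sort_values(x)
            ax.plot(sub[x], sub[metric], marker="o", label=f"type-{t}")
        ax.set_xlabel(x)
        ax.set_ylabel(metric.replace("_", " "))
        ax.set_ylim(-0.02, 1.02)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_trajectory(trajectory: pd.DataFrame, out: str | Path) -> Path:
    """Cumulative cooperation and fusion over generations for one run."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trajectory["generation"], trajectory["avg_cooperation"],
            label="average cooperation")
    ax.plot(trajectory["generation"], trajectory["avg_fusion"],
            label="average fusion")
    ax.set_xlabel("generation")
    ax.set_ylabel("cumulative average")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
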