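"""Plotting helpers for GWAS and trend reports (PNG/SVG outputs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .gwas import GwasResult  # noqa: E402
from .trends import AlleleTrajectory, TrendReport  # noqa: E402


def manhattan_plot(result: GwasResult, path: str) -> str:
    tab = result.table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(9, 3))
    offset, ticks = 0.0, {}
    for i, (chrom, sub) in enumerate(tab.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy(float)
        x = offset + (x - x.min())
        ax.scatter(x, -np.log10(sub["p"]), s=4,
                   color="#444444" if i % 2 else "#1f77b4")
        ticks[chrom] = x.mean()
        offset = x.max() + (x.max() - x.min()) * 0.02 + 1
    ax.axhline(-np.log10(result.threshold), color="red", ls="--", lw=0.8)
    ax.set_xticks(list(ticks.values()), [str(c) for c in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{result.trait} GCA")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def qq_plot(result: GwasResult, path: str) -> str:
    p = np.sort(result.table.loc[~result.table["degenerate"], "p"].to_numpy())
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def trend_plot(gca: pd.Series, eras: pd.Series, report: TrendReport, path: str) -> str:
    fig, ax = plt.subplots(figsize=(3.5, 3.2))
    order = ["AGE1", "AGE2", "AGE3"]
    data = [gca[eras[eras == era].index.intersection(gca.index)].to_numpy() for era in order]
    ax.boxplot(data, tick_labels=order)
    ax.set_ylabel(f"{report.trait} GCA")
    for row in report.comparisons.itertuples(index=False):
        if row.era_a == "AGE1" and row.era_b == "AGE3":
            ax.set_title(f"AGE1 vs AGE3: {row.significance}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def trajectory_plot(traj: AlleleTrajectory, path: str) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    order = ["AGE1", "AGE2", "AGE3"]
    bottom = np.zeros(3)
    for cls in traj.classes:
        freqs = np.array([traj.frequency(era, cls) for era in order])
        freqs = np.nan_to_num(freqs)
        axes[0].bar(order, freqs, bottom=bottom, label=cls)
        bottom += freqs
    axes[0].set_ylabel("class frequency")
    axes[0].legend(fontsize=7)
    for cls in traj.classes:
        sub = traj.per_era[traj.per_era["class"] == cls]
        axes[1].errorbar(sub["era"], sub["gca_mean"], yerr=sub["gca_sd"],
                         marker="o", capsize=3, label=cls)
    axes[1].set_ylabel(f"{traj.trait} GCA")
    axes[1].legend(fontsize=7)
    fig.suptitle(traj.snp_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def correlation_heatmap(r: pd.DataFrame, path: str) -> str:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r)), r.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
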