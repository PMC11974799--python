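"""Publication figures (violin CV, correlation panel, volcano, dendrogram,
heatmap, bars/trends). Every figure is written by
:meth:`diaprm.io.OutputWriter.save_figure` as TIFF at 300 dpi."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def cv_violin(cv_result) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = [g for g in cv_result.per_protein if len(cv_result.per_protein[g])]
    if groups:
        ax.violinplot([cv_result.per_protein[g].values for g in groups], showmedians=True)
        ax.set_xticks(range(1, len(groups) + 1), groups, rotation=45)
        for i, g in enumerate(groups, start=1):
            ax.text(i, cv_result.medians[g], f"{cv_result.medians[g]:.1f}", ha="center")
    ax.set_ylabel("CV (%)")
    fig.tight_layout()
    return fig


def correlation_panel(corr_result) -> plt.Figure:
    pairs = list(corr_result.scatter)
    n = max(len(pairs), 1)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        data = corr_result.scatter[pair]
        a, b = pair
        ax.scatter(np.log2(data[a]), np.log2(data[b]), s=4, alpha=0.4)
        ax.set_xlabel(f"log2 {a}")
        ax.set_ylabel(f"log2 {b}")
        ax.set_title(f"rho = {corr_result.rho.at[a, b]:.3f}")
    fig.tight_layout()
    return fig


def points_box(points_result) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = [g for g, v in points_result.per_group.items() if len(v)]
    if groups:
        ax.boxplot([points_result.per_group[g].values for g in groups], tick_labels=groups)
    ax.set_ylabel("MS points across peak")
    fig.tight_layout()
    return fig


def yields_bar(yields) -> plt.Figure:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    df = yields.per_group
    axes[0].bar(df["group"], df["peptides"])
    axes[0].set_ylabel("peptides")
    axes[1].bar(df["group"], df["proteins"])
    axes[1].set_ylabel("proteins")
    for ax in axes:
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def peptides_density(counts: pd.DataFrame) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in counts.groupby("group"):
        sub["peptides"].plot.density(ax=ax, label=str(g))
    ax.set_xlabel("peptides per protein")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def dendrogram_plot(tree) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(tree.linkage, labels=tree.labels, ax=ax)
    ax.set_ylabel("distance")
    fig.tight_layout()
    return fig


def correlation_heatmap(rho: pd.DataFrame) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(rho.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho.columns)), rho.columns, rotation=90)
    ax.set_yticks(range(len(rho.index)), rho.index)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    return fig


def volcano_plot(vdf: pd.DataFrame, p_thr: float, fc_thr: float) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"up": "tab:red", "down": "tab:blue", "not_significant": "lightgray"}
    for status, sub in vdf.groupby("status"):
        ax.scatter(
            sub["log2FC"], sub["neg_log10_p"], s=6, c=colors.get(status, "k"), label=status
        )
    ax.axhline(-np.log10(p_thr), ls="--", c="k", lw=0.8)
    for x in (np.log2(fc_thr), -np.log2(fc_thr)):
        ax.axvline(x, ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 P")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def ranking_plot(ranked: pd.DataFrame, group: str) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ranked["rank"], np.log2(ranked["abundance"]), lw=0.8)
    ax.set_xlabel("abundance rank")
    ax.set_ylabel("log2 abundance")
    ax.set_title(group)
    fig.tight_layout()
    return fig


def heatmap_plot(mat: pd.DataFrame, nd_marker: str = "n.d.") -> plt.Figure:
    numeric = mat.apply(pd.to_numeric, errors="coerce")
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(mat))))
    im = ax.imshow(numeric.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
    if numeric.isna().any().any():
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                if pd.isna(numeric.iat[i, j]):
                    ax.text(j, i, nd_marker, ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 abundance")
    fig.tight_layout()
    return fig


def bar_with_marks(stats_df: pd.DataFrame, title: str) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(stats_df))
    ax.bar(x, stats_df["mean"], yerr=stats_df["sd"].fillna(0), capsize=3)
    for xi, (_, row) in zip(x, stats_df.iterrows()):
        if row["mark"]:
            top = row["mean"] + (row["sd"] if np.isfinite(row["sd"]) else 0)
            ax.text(xi, top, row["mark"], ha="center", va="bottom")
    ax.set_xticks(x, stats_df["group"], rotation=45)
    ax.set_title(title)
    fig.tight_layout()
    return fig


def cld_bar(bars: pd.DataFrame, label_col: str, title: str) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(bars))
    ax.bar(x, bars["mean_copies"], yerr=bars["sd_copies"].fillna(0), capsize=3)
    for xi, (_, row) in zip(x, bars.iterrows()):
        top = row["mean_copies"] + (
            row["sd_copies"] if np.isfinite(row["sd_copies"]) else 0
        )
        ax.text(xi, top, row["letters"], ha="center", va="bottom")
    ax.set_xticks(x, bars[label_col], rotation=45)
    ax.set_ylabel("copies / nucleus")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def trend_plot(series: pd.DataFrame, title: str) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        series["group"], series["mean_copies"], yerr=series["sd_copies"].fillna(0),
        marker="o", capsize=3,
    )
    ax.set_ylabel("copies / nucleus")
    ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def enrichment_bar(enr: pd.DataFrame, top: int = 10) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    head = enr.head(top)
    if len(head):
        ax.barh(head["set_name"][::-1], -np.log10(head["p_value"])[::-1])
    ax.set_xlabel("-log10 P")
    fig.tight_layout()
    return fig


def pepseq_bar(counts: pd.DataFrame) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    sub = counts[counts["scope"] == "sample"]
    ax.bar(sub["name"], sub["matches"])
    ax.set_ylabel("peptide matches")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig
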