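"""Diagnostic plots: ordination, volcano, heatmap, normalization summaries.

All plot functions write a PNG and, where meaningful, a TSV of the plotted
coordinates so every number in a figure can be re-derived from a table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .data import SampleSheet

logger = logging.getLogger("decombine")

__all__ = ["plot_ordination", "plot_volcano", "plot_heatmap", "plot_norm_factors"]


def _condition_colors(sheet: SampleSheet) -> list[str]:
    palette = {sheet.ref_level: "tab:blue", sheet.test_level: "tab:orange"}
    return [palette[c] for c in sheet.condition]


def mds_coordinates(logcpm: np.ndarray, n_top: int = 500) -> np.ndarray:
    """Classical (Torgerson) scaling of Euclidean sample distances.

    Uses the ``n_top`` most variable genes.  Returns samples x 2.
    """
    var = logcpm.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top, logcpm.shape[0])]
    d = squareform(pdist(logcpm[top].T))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return coords


def pca_coordinates(logcpm: np.ndarray) -> np.ndarray:
    """Sample scores on the first two PCs of gene-centered log-CPM."""
    x = logcpm - logcpm.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return (vt.T * s)[:, :2]


def plot_ordination(
    logcpm: np.ndarray, sheet: SampleSheet, kind: str, outdir: Path
) -> Path | None:
    """MDS or PCA scatter of the samples, colored by condition."""
    if logcpm.shape[1] < 3:
        logger.warning("fewer than 3 samples; %s plot skipped", kind)
        return None
    if kind == "mds":
        coords = mds_coordinates(logcpm)
    elif kind == "pca":
        coords = pca_coordinates(logcpm)
    else:
        raise ValueError(f"unknown ordination kind {kind!r}")
    outdir = Path(outdir)
    df = pd.DataFrame(coords, columns=["dim1", "dim2"], index=sheet.sample_ids)
    df["condition"] = list(sheet.condition)
    df.to_csv(outdir / f"{kind}_coordinates.tsv", sep="\t", index_label="sample")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords[:, 0], coords[:, 1], c=_condition_colors(sheet))
    for i, s_id in enumerate(sheet.sample_ids):
        ax.annotate(s_id, coords[i], fontsize=7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(kind.upper())
    path = outdir / f"{kind}.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_volcano(
    table: pd.DataFrame,
    outdir: Path,
    name: str,
    padj_col: str = "padj",
    lfc_col: str = "log2_fc",
    padj_thr: float = 0.05,
    lfc_thr: float = 1.0,
) -> Path:
    """Volcano plot: log2FC versus -log10 adjusted p with threshold lines."""
    outdir = Path(outdir)
    lfc = table[lfc_col].to_numpy(dtype=float)
    padj = np.clip(table[padj_col].to_numpy(dtype=float), 1e-300, 1.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    called = (padj <= padj_thr) & (np.abs(lfc) >= lfc_thr)
    ax.scatter(lfc[~called], -np.log10(padj[~called]), s=4, c="grey", alpha=0.5)
    ax.scatter(lfc[called], -np.log10(padj[called]), s=4, c="tab:red")
    ax.axhline(-np.log10(padj_thr), ls="--", lw=0.8, c="k")
    if lfc_thr > 0:
        ax.axvline(lfc_thr, ls="--", lw=0.8, c="k")
        ax.axvline(-lfc_thr, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 padj")
    ax.set_title(f"volcano: {name}")
    path = outdir / f"volcano_{name}.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_heatmap(
    logcpm: pd.DataFrame, de_genes: list[str], sheet: SampleSheet, outdir: Path
) -> Path | None:
    """Row-z-scored log-CPM heatmap of called genes, hierarchically ordered."""
    genes = [g for g in de_genes if g in set(logcpm.index)]
    if not genes:
        logger.warning("no DE genes; heatmap skipped")
        return None
    sub = logcpm.loc[genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    z = (sub - mean) / np.where(sd > 0, sd, 1.0)
    if len(genes) > 2:
        link = hierarchy.linkage(z, method="average", metric="euclidean")
        order = hierarchy.leaves_list(link)
    else:
        order = np.arange(len(genes))
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(z[order], aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xticks(range(len(sheet.sample_ids)))
    ax.set_xticklabels(sheet.sample_ids, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(f"{len(genes)} DE genes (row z-score of log-CPM)")
    fig.colorbar(im, ax=ax, shrink=0.6)
    path = Path(outdir) / "heatmap_de_genes.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_norm_factors(factors_frame: pd.DataFrame, outdir: Path, name: str) -> Path:
    """Bar chart of per-sample normalization factors."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(range(len(factors_frame)), factors_frame["factor"])
    ax.set_xticks(range(len(factors_frame)))
    ax.set_xticklabels(factors_frame.index, rotation=90, fontsize=6)
    ax.axhline(1.0, ls="--", lw=0.8, c="k")
    ax.set_ylabel("factor")
    ax.set_title(f"{name} normalization factors")
    path = Path(outdir) / f"norm_factors_{name}.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_benchmark_curves(summary: pd.DataFrame, outdir: Path) -> Path:
    """Sensitivity and specificity line plots per preset and approach."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for metric, ax in zip(("sensitivity_mean", "specificity_mean"), axes):
        for approach, grp in summary.groupby("approach"):
            grp = grp.sort_values("preset")
            ax.plot(grp["preset"].astype(str), grp[metric], marker="o", label=approach, lw=1)
        ax.set_xlabel("dataset preset")
        ax.set_ylabel(metric.replace("_mean", ""))
    axes[1].legend(fontsize=6, loc="lower right")
    path = Path(outdir) / "benchmark_curves.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
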