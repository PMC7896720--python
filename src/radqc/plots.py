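"""Diagnostic figures: missingness dot plot, PCA panels, F_IS-vs-F_ST
scatter, heterozygosity scatter. All functions write a PNG and return
the matplotlib figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .popgen_stats import MissingnessProfile


def _pop_colors(pops):
    cmap = plt.get_cmap("tab10")
    return {p: cmap(i % 10) for i, p in enumerate(pops)}


def missingness_plot(profile: MissingnessProfile, matrix: GenotypeMatrix, path):
    """Per-individual missing-data fractions, color-coded by population."""
    fig, ax = plt.subplots(figsize=(8, 4))
    colors = _pop_colors(matrix.populations)
    x = np.arange(matrix.n_individuals)
    ax.scatter(
        x,
        profile.per_individual.to_numpy(),
        c=[colors[p] for p in matrix.pop_labels],
        s=12,
    )
    for p, c in colors.items():
        ax.scatter([], [], c=[c], label=p)
    ax.set_xlabel("individual")
    ax.set_ylabel("fraction missing")
    ax.legend(fontsize=7, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def pca_plot(result, matrix: GenotypeMatrix, path):
    """PC1 vs PC2 scores color-coded by population."""
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = _pop_colors(matrix.populations)
    s = result.scores
    for p in matrix.populations:
        rows = [i for i, lab in enumerate(matrix.pop_labels) if lab == p]
        ax.scatter(s.iloc[rows, 0], s.iloc[rows, 1], s=14, label=p,
                   color=colors[p])
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def fis_fst_plot(stats_df: pd.DataFrame, path, fst_cut=0.2, fis_cut=-0.2):
    """Per-locus pooled F_IS vs F_ST; the artifact corner highlighted."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ok = stats_df["defined"]
    fis = stats_df.loc[ok, "fis_pooled"]
    fst = stats_df.loc[ok, "fst"]
    flag = (fst > fst_cut) & (fis < fis_cut)
    ax.scatter(fis[~flag], fst[~flag], s=6, alpha=0.5, color="grey")
    ax.scatter(fis[flag], fst[flag], s=10, color="red",
               label=f"F_ST>{fst_cut}, F_IS<{fis_cut}")
    ax.set_xlabel("pooled F_IS")
    ax.set_ylabel("F_ST")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def heterozygosity_plot(stats_df: pd.DataFrame, path, flag_mask=None):
    """Observed heterozygosity in sample 1 vs sample 2 per locus."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ok = stats_df["defined"].to_numpy(dtype=bool)
    if flag_mask is None:
        flag_mask = np.zeros(len(stats_df), dtype=bool)
    flag = np.asarray(flag_mask) & ok
    plain = ok & ~flag
    ax.scatter(stats_df.loc[plain, "h1"], stats_df.loc[plain, "h2"],
               s=6, alpha=0.5, color="grey")
    ax.scatter(stats_df.loc[flag, "h1"], stats_df.loc[flag, "h2"],
               s=10, color="red")
    ax.set_xlabel("observed het, sample 1")
    ax.set_ylabel("observed het, sample 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
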