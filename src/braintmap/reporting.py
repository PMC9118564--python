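"""Tabular and heat-map reporting of the two-stage results.

Every number that appears in a rendered figure is also written to a CSV, so
the figures are testable numerically and nothing is figure-only.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering only

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .datatypes import EffectMap, GeneCorrelationResults
from .errors import InputError


def heatmap_matrices(
    results: GeneCorrelationResults, genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pivot stage-2 results into contrast x gene matrices.

    Returns (neglog10p, r, significant) DataFrames with contrasts as rows
    and genes as columns (both sorted). ``genes`` defaults to the
    all-contrast intersection; pass an explicit list to plot other genes.
    """
    if genes is None:
        genes = results.intersection()
    if not genes:
        raise InputError("no genes to render (empty selection)")
    sub = results.table[results.table["gene"].isin(genes)].copy()
    sub["neglog10p"] = -np.log10(sub["p"].clip(lower=1e-300))
    neglog = sub.pivot_table(index="contrast", columns="gene", values="neglog10p")
    rmat = sub.pivot_table(index="contrast", columns="gene", values="r")
    sig = (
        sub.pivot_table(
            index="contrast", columns="gene", values="significant", aggfunc="any"
        )
        .fillna(False)
        .astype(bool)
    )
    cols = sorted(neglog.columns)
    return (
        neglog.sort_index()[cols],
        rmat.sort_index()[cols],
        sig.sort_index()[cols],
    )


def render_heatmaps(
    results: GeneCorrelationResults,
    out_prefix: str | Path,
    genes: list[str] | None = None,
) -> dict[str, Path]:
    """Write the gene-finding heat map (PNG) plus its backing CSV matrices.

    Cells are colored by -log10(p) of the gene-contrast correlation; each
    cell is annotated with the Pearson r rounded to two decimals, and
    significant cells (family-wise corrected) carry an "X" mark.
    """
    neglog, rmat, sig = heatmap_matrices(results, genes)
    out_prefix = Path(out_prefix)
    paths = {
        "neglog10p_csv": out_prefix.with_name(out_prefix.name + "_neglog10p.csv"),
        "r_csv": out_prefix.with_name(out_prefix.name + "_r.csv"),
        "significant_csv": out_prefix.with_name(out_prefix.name + "_significant.csv"),
        "png": out_prefix.with_name(out_prefix.name + ".png"),
    }
    neglog.to_csv(paths["neglog10p_csv"], float_format="%.17g")
    rmat.to_csv(paths["r_csv"], float_format="%.17g")
    sig.to_csv(paths["significant_csv"])

    annot = rmat.round(2).astype(str)
    annot = annot.where(~sig, annot + "\nX")
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.9 * neglog.shape[1] + 2), 0.6 * neglog.shape[0] + 2)
    )
    sns.heatmap(
        neglog,
        annot=annot,
        fmt="",
        cmap="viridis",
        cbar_kws={"label": r"$-\log_{10}(p)$"},
        ax=ax,
    )
    ax.set_xlabel("gene")
    ax.set_ylabel("diagnostic comparison")
    fig.tight_layout()
    fig.savefig(paths["png"], dpi=150)
    plt.close(fig)
    return paths


def roi_summary_table(effect_maps: list[EffectMap], top_k: int = 10) -> pd.DataFrame:
    """Union of each contrast's top_k ROIs by -log10(p), as a sparse wide
    table: rows are ROI labels (sorted), one column per contrast, cells
    carry -log10(p) only where the ROI is in that contrast's top_k."""
    if top_k < 1:
        raise InputError(f"top_k must be >= 1, got {top_k}")
    if not effect_maps:
        raise InputError("need at least one effect map")
    cols = {}
    for m in effect_maps:
        top = m.table.nlargest(top_k, "neglog10p")["neglog10p"]
        cols[m.contrast.name] = top
    out = pd.DataFrame(cols).sort_index()
    out.index.name = "roi_label"
    return out


def render_effect_heatmap(
    effect_maps: list[EffectMap], out_prefix: str | Path
) -> dict[str, Path]:
    """ROI x contrast -log10(p) heat map (a flat rendering of the brain
    maps) with its backing CSV."""
    if not effect_maps:
        raise InputError("need at least one effect map")
    mat = pd.DataFrame(
        {m.contrast.name: m.table["neglog10p"] for m in effect_maps}
    ).sort_index()
    mat.index.name = "roi_label"
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_name(out_prefix.name + "_neglog10p.csv")
    png_path = out_prefix.with_name(out_prefix.name + ".png")
    mat.to_csv(csv_path, float_format="%.17g")
    fig, ax = plt.subplots(figsize=(8, max(4.0, 0.05 * len(mat) + 2)))
    sns.heatmap(mat, cmap="viridis", cbar_kws={"label": r"$-\log_{10}(p)$"}, ax=ax)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return {"csv": csv_path, "png": png_path}
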