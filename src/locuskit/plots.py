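"""Publication-quality static figures for association results.

Provides stacked regional-association panels with LD coloring and a gene
track (LocusZoom style), genome-wide Manhattan plots on cumulative
chromosome coordinates, QQ plots with the genomic inflation factor
lambda_GC, and LD heatmaps.  Rendering is deterministic: fixed inputs and
configuration reproduce identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap, Normalize
from scipy import stats

from . import genemodels, ld
from .ld import GenotypePanel
from .sumstats import chrom_rank

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
#: median of the 1-df chi-square distribution, the null median for lambda_GC
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

SIGNIFICANCE_COLOR = "purple"
GENE_GUIDE_COLOR = "gold"
MISSING_LD_COLOR = "#B8B8B8"


class EmptyRegionError(ValueError):
    """No data points fall inside the requested region."""


@dataclass
class PlotConfig:
    """Shared figure options.

    ``threshold`` is the genome-wide significance level drawn as the
    purple horizontal line; ``ld_bins`` switches the continuous
    grey-to-red LD colormap to the classic binned palette;
    ``highlight_gene`` draws yellow guide lines at that gene's start and
    end; ``y_cap`` truncates extreme -log10 P values with a break marker.
    """

    threshold: float = GENOME_WIDE_P
    ld_bins: bool = False
    highlight_gene: str | None = None
    panel_height: float = 1.6
    width: float = 8.0
    dpi: int = 150
    point_size: float = 9.0
    y_cap: float | None = None
    gap: int = 10_000_000  # Manhattan inter-chromosome gap, bp
    chrom_colors: tuple[str, str] = ("#2E4A7A", "#7A9CC6")

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("significance threshold must be in (0, 1)")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")


def ld_colormap(binned: bool = False):
    """Light-grey-to-red colormap (and norm) for r² in [0, 1].

    The continuous map encodes LD as the intensity of red; ``binned``
    yields the conventional five-bin palette instead.
    """
    if binned:
        cmap = LinearSegmentedColormap.from_list(
            "ld_binned",
            ["#E8E8E8", "#F6C3C3", "#EE8A8A", "#E65151", "#DD1818"],
            N=5,
        )
        norm = BoundaryNorm([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], cmap.N)
    else:
        cmap = LinearSegmentedColormap.from_list("ld", ["#E8E8E8", "#FF0000"])
        norm = Normalize(vmin=0.0, vmax=1.0)
    return cmap, norm


def lambda_gc(pvalues) -> float:
    """Genomic inflation factor: median observed chi-square (1 df,
    from two-sided P) divided by the null median 0.4549364."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no P values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chi2 = stats.norm.isf(p / 2.0) ** 2
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def manhattan_coordinates(
    sumstats: pd.DataFrame, gap: int = 10_000_000
) -> tuple[np.ndarray, dict[str, float]]:
    """Cumulative x coordinates for a Manhattan plot.

    Chromosomes are laid end to end in canonical order; the offset of a
    chromosome is the running sum of previous chromosomes' maximum
    positions plus one ``gap`` per boundary.  Returns the per-record x
    array (aligned with the input) and each chromosome's label midpoint.
    """
    chroms = sumstats["chrom"].astype(str)
    pos = sumstats["pos"].to_numpy(dtype=float)
    order = sorted(chroms.unique(), key=lambda c: (chrom_rank([c])[0], c))
    x = np.empty(len(sumstats))
    midpoints: dict[str, float] = {}
    offset = 0.0
    for i, c in enumerate(order):
        mask = (chroms == c).to_numpy()
        if i > 0:
            offset += gap
        x[mask] = pos[mask] + offset
        midpoints[c] = offset + (pos[mask].min() + pos[mask].max()) / 2.0
        offset += pos[mask].max()
    return x, midpoints


def _save(fig, out: str | Path | None, dpi: int):
    if out is not None:
        fig.savefig(out, dpi=dpi)
        logger.info("wrote figure %s", out)
    return fig


def _apply_ycap(y: np.ndarray, ax, cap: float | None) -> np.ndarray:
    if cap is None:
        return y
    capped = np.minimum(y, cap)
    if np.any(y > cap):
        ax.axhline(cap, color="0.4", linestyle=":", linewidth=0.8)
    return capped


def plot_locus(
    traits: Sequence[tuple[str, pd.DataFrame]],
    region: tuple[str, int, int],
    panel: GenotypePanel | None = None,
    genes: Sequence[genemodels.GeneModel] | None = None,
    config: PlotConfig | None = None,
    out: str | Path | None = None,
):
    """Stacked regional-association panels with LD coloring + gene track.

    One scatter panel per trait (x = position, y = -log10 P) shares the
    x-axis with a packed gene track at the bottom.  In each panel the
    index SNP (minimum P in the region, or a sentinel named per trait as
    ``(label, table, sentinel_snp_id)``) is labelled and marked with a
    diamond; other points are colored by r² against it, computed on the
    fly from ``panel``.  Missing r² renders grey.  The purple line marks
    genome-wide significance; yellow lines mark ``config.highlight_gene``
    boundaries.  Any number of traits is accepted.
    """
    config = config or PlotConfig()
    chrom, start, end = region
    chrom = str(chrom)
    if not start < end:
        raise ValueError("region start must be < end")

    subsets = []
    for entry in traits:
        label, table = entry[0], entry[1]
        sentinel = entry[2] if len(entry) > 2 else None
        sub = table[
            (table["chrom"].astype(str) == chrom)
            & (table["pos"] >= start)
            & (table["pos"] <= end)
        ]
        subsets.append((label, sub, sentinel))
    if all(sub.empty for _, sub, _ in subsets):
        raise EmptyRegionError(f"no SNPs in {chrom}:{start}-{end} for any trait")

    n_panels = len(subsets)
    fig, axes = plt.subplots(
        n_panels + 1,
        1,
        sharex=True,
        figsize=(config.width, config.panel_height * (n_panels + 1)),
        gridspec_kw={"height_ratios": [3.0] * n_panels + [2.0]},
        squeeze=False,
    )
    axes = axes[:, 0]
    cmap, norm = ld_colormap(config.ld_bins)

    for ax, (label, sub, sentinel) in zip(axes[:-1], subsets):
        ax.set_ylabel(r"$-\log_{10}\,P$", fontsize=8)
        ax.axhline(-np.log10(config.threshold), color=SIGNIFICANCE_COLOR,
                   linewidth=1.0, zorder=1)
        ax.text(0.995, 0.92, label, transform=ax.transAxes,
                ha="right", va="top", fontsize=8)
        if sub.empty:
            continue
        y = _apply_ycap(sub["neglog10p"].to_numpy(dtype=float), ax, config.y_cap)
        pos = sub["pos"].to_numpy(dtype=float)

        if sentinel is not None:
            idx_row = int(np.flatnonzero(sub["snp_id"].to_numpy() == sentinel)[0])
        else:
            idx_row = int(np.argmin(sub["p"].to_numpy()))

        colors = np.full(len(sub), MISSING_LD_COLOR, dtype=object)
        if panel is not None:
            try:
                key = (chrom, int(sub["pos"].iloc[idx_row]))
                ridx = panel.region_indices(chrom, start, end)
                res = ld.ld_r2(panel, key, targets=ridx)
                pos2r2 = dict(zip(
                    panel.variants["pos"].iloc[res.target_indices], res.r2
                ))
                r2 = np.array([pos2r2.get(int(p), np.nan) for p in sub["pos"]])
                for k in np.flatnonzero(np.isfinite(r2)):
                    colors[k] = cmap(norm(r2[k]))
            except KeyError:
                logger.warning("index SNP %s not in reference panel; grey points",
                               sub["snp_id"].iloc[idx_row])
        mask = np.ones(len(sub), dtype=bool)
        mask[idx_row] = False
        ax.scatter(pos[mask], y[mask], s=config.point_size,
                   c=list(colors[mask]), linewidths=0, zorder=2)
        ax.scatter([pos[idx_row]], [y[idx_row]], s=config.point_size * 3.2,
                   marker="D", c=SIGNIFICANCE_COLOR, edgecolors="black",
                   linewidths=0.4, zorder=3)
        ax.annotate(str(sub["snp_id"].iloc[idx_row]),
                    (pos[idx_row], y[idx_row]),
                    textcoords="offset points", xytext=(4, 4), fontsize=7)
        ax.set_ylim(bottom=0)

    # gene track
    track_ax = axes[-1]
    track_ax.set_yticks([])
    track_ax.set_xlabel(f"chromosome {chrom} position (bp)", fontsize=8)
    highlight_span = None
    if genes:
        span = max(1.0, float(end - start))
        char_w = span * 0.008  # label width per character, axis units
        geom, layout = genemodels.gene_track_geometry(
            list(genes), label_char_width=char_w, padding=span * 0.005
        )
        row_h = 1.0
        for row, s, e in geom.exon_boxes:
            track_ax.add_patch(
                plt.Rectangle((s, -row * row_h - 0.30), e - s + 1, 0.6,
                              facecolor="#2E4A7A", edgecolor="none")
            )
        for row, s, e in geom.intron_lines:
            track_ax.plot([s, e], [-row * row_h] * 2, color="#2E4A7A",
                          linewidth=0.7)
        for row, x0, text in geom.labels:
            track_ax.text(x0, -row * row_h + 0.38, text, fontsize=6, va="bottom")
        track_ax.set_ylim(-(layout.n_rows - 0.2) * row_h - 0.6, 1.1)
        if config.highlight_gene:
            for g in genes:
                if g.gene_name == config.highlight_gene:
                    highlight_span = (g.start, g.end)
                    break
    if highlight_span is not None:
        for ax in axes:
            for xg in highlight_span:
                ax.axvline(xg, color=GENE_GUIDE_COLOR, linewidth=1.0, zorder=0)

    track_ax.set_xlim(start, end)
    fig.align_ylabels(axes[:-1])
    fig.subplots_adjust(hspace=0.25)
    return _save(fig, out, config.dpi)


def plot_manhattan(
    sumstats: pd.DataFrame,
    config: PlotConfig | None = None,
    out: str | Path | None = None,
):
    """Genome-wide Manhattan plot on cumulative coordinates."""
    config = config or PlotConfig()
    if sumstats.empty:
        raise ValueError("empty summary-statistics table")
    x, midpoints = manhattan_coordinates(sumstats, gap=config.gap)
    chroms = sumstats["chrom"].astype(str)

    fig, ax = plt.subplots(figsize=(config.width * 1.4, config.panel_height * 2))
    for i, c in enumerate(midpoints):
        mask = (chroms == c).to_numpy()
        y = _apply_ycap(
            sumstats.loc[mask, "neglog10p"].to_numpy(dtype=float), ax, config.y_cap
        )
        ax.scatter(x[mask], y, s=config.point_size * 0.6,
                   c=config.chrom_colors[i % 2], linewidths=0)
    ax.axhline(-np.log10(config.threshold), color=SIGNIFICANCE_COLOR, linewidth=1.0)
    ax.set_xticks(list(midpoints.values()))
    ax.set_xticklabels(list(midpoints), fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,P$")
    ax.set_ylim(bottom=0)
    return _save(fig, out, config.dpi)


def plot_qq(
    pvalues,
    config: PlotConfig | None = None,
    out: str | Path | None = None,
) -> tuple[matplotlib.figure.Figure, float]:
    """QQ plot of observed vs expected -log10 P; returns (fig, lambda_GC).

    Expected quantiles are -log10((i - 0.5) / n) for rank i of n.
    """
    config = config or PlotConfig()
    p = np.sort(np.asarray(pvalues, dtype=float))
    lam = lambda_gc(p)  # validates domain and emptiness
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(p)[::-1]

    fig, ax = plt.subplots(figsize=(4.0, 4.0))
    lim = float(max(expected.max(), observed.max())) * 1.05
    ax.plot([0, lim], [0, lim], color="0.5", linewidth=0.8)
    ax.scatter(expected, observed, s=6, c="#2E4A7A", linewidths=0)
    ax.set_xlabel(r"expected $-\log_{10}\,P$")
    ax.set_ylabel(r"observed $-\log_{10}\,P$")
    ax.text(0.05, 0.93, rf"$\lambda_{{GC}} = {lam:.3f}$",
            transform=ax.transAxes, fontsize=9)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    _save(fig, out, config.dpi)
    return fig, lam


def plot_ld_heatmap(
    matrix: np.ndarray,
    positions=None,
    config: PlotConfig | None = None,
    rotate: bool = False,
    out: str | Path | None = None,
):
    """Lower-triangle r² heatmap on the grey-to-red LD scale.

    ``rotate`` draws the conventional 45-degree triangle.  The input must
    be symmetric (NaN-aware) or a validation error is raised.
    """
    config = config or PlotConfig()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("LD matrix must be square")
    both = np.isfinite(m) & np.isfinite(m.T)
    if not (np.allclose(m[both], m.T[both], atol=1e-9)
            and np.array_equal(np.isfinite(m), np.isfinite(m.T))):
        raise ValueError("LD matrix is not symmetric")

    n = m.shape[0]
    cmap, norm = ld_colormap(config.ld_bins)
    cmap = cmap.copy()
    cmap.set_bad(MISSING_LD_COLOR)
    fig, ax = plt.subplots(figsize=(config.width, config.width * (0.55 if rotate else 1.0)))
    if rotate:
        lower = np.ma.masked_array(m, mask=~np.tri(n, dtype=bool))
        a = np.arange(n + 1)
        xc = (a[:, None] + a[None, :]) / 2.0
        yc = (a[:, None] - a[None, :]) / 2.0
        ax.pcolormesh(xc, yc, lower.T, cmap=cmap, norm=norm, rasterized=True)
        ax.set_ylim(0, n / 2.0)
        ax.set_yticks([])
    else:
        lower = np.ma.masked_array(m, mask=~np.tri(n, dtype=bool))
        ax.imshow(lower, cmap=cmap, norm=norm, origin="upper",
                  interpolation="nearest", rasterized=True)
    ax.set_xlabel(f"{n} variants" if positions is None else "position (bp)")
    if positions is not None and not rotate:
        ticks = np.linspace(0, n - 1, min(6, n)).astype(int)
        ax.set_xticks(ticks)
        ax.set_xticklabels([f"{int(positions[t]):,}" for t in ticks],
                           fontsize=7, rotation=45)
    return _save(fig, out, config.dpi)
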