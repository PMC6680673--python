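"""Matplotlib rendering of the plot models to SVG, PNG, or PDF.

The models carry every encoding decision; this module only draws. Output is
deterministic for a fixed matplotlib version: SVG element ids are salted
with a fixed string and date metadata is stripped, so re-rendering the same
model yields byte-identical files.

In SVG output every rain-plot droplet is a circle mark tagged with a unique
``droplet-<row>-<col>`` id, so figures are machine-checkable (one mark per
grid cell).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import Normalize
from matplotlib.patches import Circle

from .core_io import SchemaError
from .plotmodel import (
    BarScatterModel,
    ManhattanModel,
    PairedHeatmapModel,
    RainPlotModel,
)

__all__ = ["render", "BETA_CMAP", "P_CMAP"]

BETA_CMAP = "RdBu_r"  # diverging blue-white-red, CVD-safe
P_CMAP = "viridis"
_POS_COLOR = "#b2182b"
_NEG_COLOR = "#2166ac"
_HASHSALT = "rainplot"

_EXTENSIONS = (".svg", ".png", ".pdf")


def _render_rain(model: RainPlotModel) -> plt.Figure:
    n_rows, n_cols = len(model.rows), len(model.cols)
    fig_w = max(3.0, 0.35 * n_cols + 2.2)
    fig_h = max(2.5, 0.28 * n_rows + 1.6)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    norm = Normalize(*model.color_limits)
    cmap = plt.get_cmap(BETA_CMAP)
    for cell in model.cells:
        circ = Circle(
            (cell.col + 0.5, n_rows - cell.row - 0.5),
            radius=cell.radius,
            facecolor=cmap(norm(cell.fill_value)),
            edgecolor="0.4",
            linewidth=0.4,
        )
        circ.set_gid(f"droplet-{cell.row}-{cell.col}")
        ax.add_patch(circ)
    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_rows)
    ax.set_aspect("equal")
    ax.set_xticks(np.arange(n_cols) + 0.5)
    ax.set_xticklabels(model.cols, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(n_rows - np.arange(n_rows) - 0.5)
    ax.set_yticklabels(model.rows, fontsize=6)
    ax.tick_params(length=0)
    for spine in ax.spines.values():
        spine.set_visible(False)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    cbar = fig.colorbar(sm, ax=ax, shrink=0.6, pad=0.02)
    cbar.set_label("beta per 1-SD log abundance", fontsize=7)
    cbar.ax.tick_params(labelsize=6)
    ax.set_title(
        f"rain plot: droplet size = -log10(P), capped at {model.cap:.2g}",
        fontsize=8,
    )
    fig.tight_layout()
    return fig


def _render_manhattan(model: ManhattanModel) -> plt.Figure:
    n = len(model.facets)
    fig, axes = plt.subplots(
        n, 1, figsize=(7.0, 1.4 * n + 0.8), sharex=True, sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, outcome in zip(axes, model.facets):
        pts = model.facet_points(outcome)
        for direction, color in ((1, _POS_COLOR), (-1, _NEG_COLOR), (0, "0.5")):
            sub = pts[pts["direction"] == direction]
            if len(sub):
                ax.scatter(sub["mz"], sub["y"], s=6, c=color, linewidths=0)
        ax.axhline(model.threshold_line, color="0.3", linewidth=0.7, linestyle="--")
        ax.set_ylim(*model.ylim)
        ax.set_ylabel(outcome, fontsize=6, rotation=0, ha="right", va="center")
        ax.tick_params(labelsize=6)
    axes[-1].set_xlabel(
        "m/z" if model.x_mode == "mz" else "m/z rank", fontsize=8
    )
    fig.suptitle("-log10(P) by mass-to-charge ratio", fontsize=9)
    fig.tight_layout()
    return fig


def _render_barscatter(model: BarScatterModel) -> plt.Figure:
    n = len(model.metabolite_ids)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.12 * n + 1.5), 3.4))
    x = np.arange(n)
    colors = [_POS_COLOR if b > 0 else _NEG_COLOR for b in model.bar_heights]
    ax.bar(x, model.bar_heights, color=colors, width=0.8)
    ax.axhline(0, color="0.2", linewidth=0.6)
    ax.set_ylabel("beta", fontsize=8)
    ax.set_xlabel("metabolite", fontsize=8)
    ax2 = ax.twinx()
    ax2.scatter(x, model.dot_values, s=8, c="0.15", zorder=3, linewidths=0)
    ax2.set_ylabel("-log10(P)", fontsize=8)
    ax.set_title(model.outcome, fontsize=9)
    ax.tick_params(labelsize=6)
    ax2.tick_params(labelsize=6)
    fig.tight_layout()
    return fig


def _render_heatmap_pair(model: PairedHeatmapModel) -> plt.Figure:
    n_rows, n_cols = model.fills_beta.shape
    fig_h = max(2.5, 0.22 * n_rows + 1.5)
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(max(5.0, 0.6 * n_cols + 3.5), fig_h)
    )
    im1 = ax1.imshow(
        model.fills_beta,
        cmap=BETA_CMAP,
        vmin=model.beta_limits[0],
        vmax=model.beta_limits[1],
        aspect="auto",
        interpolation="nearest",
    )
    ax1.set_title("beta", fontsize=8)
    im2 = ax2.imshow(
        model.fills_p,
        cmap=P_CMAP,
        vmin=model.p_limits[0],
        vmax=model.p_limits[1],
        aspect="auto",
        interpolation="nearest",
    )
    ax2.set_title("-log10(P)", fontsize=8)
    for ax in (ax1, ax2):
        ax.set_xticks(np.arange(n_cols))
        ax.set_xticklabels(model.cols, rotation=45, ha="right", fontsize=6)
        ax.set_yticks([])
        ax.tick_params(length=0)
    fig.colorbar(im1, ax=ax1, shrink=0.7)
    fig.colorbar(im2, ax=ax2, shrink=0.7)
    fig.tight_layout()
    return fig


_RENDERERS = {
    RainPlotModel: _render_rain,
    ManhattanModel: _render_manhattan,
    BarScatterModel: _render_barscatter,
    PairedHeatmapModel: _render_heatmap_pair,
}


def render(model, path: str | Path) -> Path:
    """Draw a plot model to ``path``; format from the extension
    (svg, png, or pdf). Returns the written path."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _EXTENSIONS:
        raise SchemaError(
            f"unknown output extension {ext!r}; use one of {_EXTENSIONS}"
        )
    renderer = None
    for cls, fn in _RENDERERS.items():
        if isinstance(model, cls):
            renderer = fn
            break
    if renderer is None:
        raise SchemaError(f"cannot render object of type {type(model).__name__}")

    with matplotlib.rc_context({"svg.hashsalt": _HASHSALT}):
        fig = renderer(model)
        try:
            metadata = None
            if ext == ".svg":
                metadata = {"Date": None}
            elif ext == ".pdf":
                metadata = {"CreationDate": None}
            fig.savefig(path, metadata=metadata)
        finally:
            plt.close(fig)
    return path
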