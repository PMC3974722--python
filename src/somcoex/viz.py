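"""Map and profile plots, each with a sidecar TSV of the plotted numbers.

Component planes: one image per time sample, every hexagon colored by
that unit's weight component for the sample, blue (low) to red (high).
The color scale is anchored to the [0, 1] fraction domain for the whole
run, so a given color means the same expression fraction in every
image.  Gene-location maps place gene labels in their units, with
optional highlight sets.  Every renderer also writes the numbers it
plotted as a TSV so tests (and users) can assert on data, not pixels.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import RegularPolygon

from .consistency import BmuTable
from .io_formats import ExpressionDataset
from .som import HexGrid, SomModel

__all__ = ["render_component_planes", "render_gene_map", "plot_profiles"]

_HEX_RADIUS = 1.0 / math.sqrt(3.0)  # circumradius for unit-edge spacing


def _draw_hex_grid(ax, grid: HexGrid, face_colors=None):
    xy = grid.coords()
    for k, (x, y) in enumerate(xy):
        color = face_colors[k] if face_colors is not None else "white"
        ax.add_patch(
            RegularPolygon(
                (x, y),
                numVertices=6,
                radius=_HEX_RADIUS,
                orientation=0.0,
                facecolor=color,
                edgecolor="gray",
                linewidth=0.3,
            )
        )
    ax.set_xlim(-1, grid.n_cols + 1)
    ax.set_ylim(-1, grid.n_rows * math.sqrt(3) / 2 + 1)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # unit 1 at the top-left, matching the label order
    ax.axis("off")


def _write_sidecar(path: Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def render_component_planes(
    model: SomModel,
    sample_times: np.ndarray,
    phase_labels: list[str] | None,
    out_dir: str | Path,
    vmin: float = 0.0,
    vmax: float = 1.0,
) -> list[Path]:
    """One blue→red map per time sample, colored by unit weights.

    Returns the image paths (``plane_###.png``); the full weight matrix is
    written alongside as ``component_planes.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = plt.get_cmap("jet")
    paths = []
    for j in range(model.dim):
        fig, ax = plt.subplots(figsize=(5, 5))
        vals = model.weights[:, j]
        normed = np.clip((vals - vmin) / (vmax - vmin or 1.0), 0, 1)
        _draw_hex_grid(ax, model.grid, face_colors=cmap(normed))
        title = f"t = {sample_times[j]:g} min"
        if phase_labels is not None:
            title += f" ({phase_labels[j]})"
        ax.set_title(title)
        p = out_dir / f"plane_{j:03d}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    _write_sidecar(
        out_dir / "component_planes.tsv",
        ["unit"] + [f"t{sample_times[j]:g}" for j in range(model.dim)],
        (
            [label] + [repr(float(v)) for v in row]
            for label, row in enumerate(model.weights, start=1)
        ),
    )
    return paths


def render_gene_map(
    table: BmuTable,
    grid: HexGrid,
    highlight_sets: dict[str, list[str]] | None = None,
    out_path: str | Path = "gene_map.png",
) -> Path:
    """Hex-grid plot with gene labels in their units; highlights colored.

    Co-located genes are stacked within the hexagon, never dropped.  The
    gene → unit table is written next to the image as ``<stem>.tsv``.
    """
    out_path = Path(out_path)
    highlight_sets = highlight_sets or {}
    fig, ax = plt.subplots(figsize=(10, 10))
    _draw_hex_grid(ax, grid)
    xy = grid.coords()
    colors = plt.get_cmap("tab10")
    gene_color = {}
    for ci, (name, genes) in enumerate(highlight_sets.items()):
        for g in genes:
            gene_color[g] = colors(ci % 10)
    for unit, members in sorted(table.clusters.items()):
        x, y = xy[unit - 1]
        for k, gene in enumerate(sorted(members)):
            ax.text(
                x,
                y + (k - (len(members) - 1) / 2) * 0.22,
                gene,
                fontsize=4,
                ha="center",
                va="center",
                color=gene_color.get(gene, "black"),
            )
    if highlight_sets:
        handles = [
            plt.Line2D([], [], marker="s", linestyle="", color=colors(i % 10), label=name)
            for i, name in enumerate(highlight_sets)
        ]
        ax.legend(handles=handles, loc="upper right")
    ax.set_title(f"Gene locations — {table.database_name}")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    _write_sidecar(
        out_path.with_suffix(".tsv"),
        ["gene", "unit"],
        sorted(table.assignments.items()),
    )
    return out_path


def plot_profiles(
    datasets: list[ExpressionDataset],
    genes: list[str],
    out_path: str | Path,
) -> Path:
    """Expression-profile lines over time, one panel per database.

    X ticks carry sampling time and cell-cycle phase when available.
    Unknown genes raise a ValueError listing the missing ids; the plotted
    series are written as ``<stem>.tsv``.
    """
    out_path = Path(out_path)
    if not genes:
        raise ValueError("empty gene set")
    missing = sorted(
        {g for ds in datasets for g in genes if g not in ds.gene_ids}
    )
    if missing:
        raise ValueError(f"genes not present: {missing}")
    fig, axes = plt.subplots(
        len(datasets), 1, figsize=(8, 2.6 * len(datasets)), squeeze=False
    )
    sidecar_rows = []
    for ax, ds in zip(axes[:, 0], datasets):
        for g in genes:
            row = ds.values[ds.gene_ids.index(g)]
            ax.plot(ds.sample_times, row, marker="o", markersize=2, label=g)
            for t, v in zip(ds.sample_times, row):
                sidecar_rows.append([ds.database_name, g, f"{t:g}", repr(float(v))])
        ticks = ds.sample_times[:: max(1, len(ds.sample_times) // 10)]
        ax.set_xticks(ticks)
        if ds.phase_labels is not None:
            labels = [
                f"{t:g}\n{ds.phase_labels[list(ds.sample_times).index(t)]}"
                for t in ticks
            ]
            ax.set_xticklabels(labels, fontsize=6)
        ax.set_title(ds.database_name, fontsize=8)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    _write_sidecar(
        out_path.with_suffix(".tsv"),
        ["database", "gene", "time_min", "value"],
        sidecar_rows,
    )
    return out_path
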