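"""Figures and the HTML report.

Every figure function returns the matplotlib figure together with a
machine-readable sidecar (summary table or layout) so tests can assert on
data rather than pixels, and so the expression heatmap's cell order can
be imposed on the index heatmap. All figures are deterministic given the
experiment, grouping, and any seeds.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .embed_cluster import Embedding, correlation_distance, hcluster  # noqa: E402
from .errors import InputError  # noqa: E402
from .experiment import AnalysisLog, Experiment  # noqa: E402
from .grouping import Grouping  # noqa: E402
from .scrapbook import Scrapbook, ScrapbookEntry  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402

MISSING_COLOR = "#BBBBBB"


@dataclass
class HeatmapLayout:
    """Cell/gene order and per-cell colour bar shared across heatmaps."""

    cell_order: list[str]
    gene_order: list[str]
    color_bar: list[str]  # one colour per cell, aligned with cell_order


def _group_values(
    exp: Experiment, gene: str, grouping: Grouping
) -> list[tuple[str, str, np.ndarray]]:
    col = exp.matrix[gene]
    out = []
    for g in grouping.groups:
        cells = [c for c in exp.cells if c in g.members]
        vals = col.loc[cells].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        out.append((g.label, g.color, vals))
    return out


def violin_figure(
    exp: Experiment, gene: str, grouping: Grouping
) -> tuple[plt.Figure, pd.DataFrame]:
    """One violin per non-empty group (grouping order, group colours).

    Groups too small or too degenerate for a density (n < 2 or zero
    variance) are drawn as points. Returns the figure and a summary table
    with n, median, and quartiles per group.
    """
    if gene not in exp.matrix.columns:
        raise InputError(f"unknown gene: {gene!r}")
    grouping.validate_against(exp.cells)
    data = _group_values(exp, gene, grouping)
    fig, ax = plt.subplots(figsize=(1.2 * max(4, len(data)), 4))
    rows = []
    for pos, (label, color, vals) in enumerate(data, start=1):
        if vals.size >= 2 and np.std(vals) > 0:
            parts = ax.violinplot([vals], positions=[pos], showmedians=True)
            for body in parts["bodies"]:
                body.set_facecolor(color)
                body.set_alpha(0.7)
        elif vals.size:
            ax.plot([pos] * vals.size, vals, "o", color=color)
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append(
            {"group": label, "n": int(vals.size), "median": med, "q1": q1, "q3": q3}
        )
    ax.set_xticks(range(1, len(data) + 1))
    ax.set_xticklabels([d[0] for d in data], rotation=30, ha="right")
    ax.set_ylabel(f"{gene} ({exp.stage})")
    ax.set_title(gene)
    fig.tight_layout()
    return fig, pd.DataFrame(rows)


def _leaf_order(matrix: pd.DataFrame) -> list:
    """Hierarchical leaf order of rows (correlation distance, complete);
    falls back to input order when a distance is undefined."""
    if matrix.shape[0] < 3:
        return list(matrix.index)
    try:
        dist = correlation_distance(matrix)
    except InputError:
        return list(matrix.index)
    tree = hcluster(dist, "complete")
    leaves = hierarchy.leaves_list(tree.linkage_matrix)
    return [matrix.index[i] for i in leaves]


def expression_heatmap(
    exp: Experiment,
    grouping: Grouping,
    within_group_order: str = "cluster",
    cluster_genes: bool = True,
) -> tuple[plt.Figure, HeatmapLayout]:
    """Cells ordered by group (grouping order), optionally leaf-ordered
    within each group; genes optionally leaf-ordered. A per-cell colour
    bar marks group membership; the returned layout lets the index
    heatmap reuse the identical order.
    """
    if within_group_order not in ("cluster", "none"):
        raise InputError(f"within_group_order must be 'cluster' or 'none'")
    grouping.validate_against(exp.cells)
    cell_order: list[str] = []
    color_bar: list[str] = []
    for g in grouping.groups:
        members = [c for c in exp.cells if c in g.members]
        if within_group_order == "cluster":
            members = _leaf_order(exp.matrix.loc[members])
        cell_order.extend(members)
        color_bar.extend([g.color] * len(members))
    gene_order = list(exp.matrix.columns)
    if cluster_genes and len(gene_order) >= 3:
        gene_order = _leaf_order(exp.matrix[gene_order].T)
    layout = HeatmapLayout(cell_order, [str(g) for g in gene_order], color_bar)

    data = exp.matrix.loc[cell_order, gene_order].to_numpy(dtype=float)
    fig = _render_heatmap(
        data,
        color_bar,
        row_labels=cell_order,
        col_labels=[str(g) for g in gene_order],
        diverging=exp.stage == "z_transformed",
        title=f"expression ({exp.stage})",
    )
    return fig, layout


def index_heatmap(exp: Experiment, layout: HeatmapLayout) -> plt.Figure:
    """Index-sort marker heatmap in the exact cell order (and colour bar)
    of a previously computed expression heatmap; missing marker values
    are rendered in a dedicated missing colour."""
    if exp.index_markers is None:
        raise InputError("no index data joined; run join_index first")
    data = exp.index_markers.loc[layout.cell_order].to_numpy(dtype=float)
    return _render_heatmap(
        data,
        layout.color_bar,
        row_labels=layout.cell_order,
        col_labels=[str(m) for m in exp.index_markers.columns],
        diverging=False,
        title="index-sort markers",
    )


def _render_heatmap(
    data: np.ndarray,
    color_bar: Sequence[str],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    diverging: bool,
    title: str,
) -> plt.Figure:
    fig, (ax_bar, ax) = plt.subplots(
        1, 2, figsize=(8, 6), gridspec_kw={"width_ratios": [1, 30]}
    )
    if diverging:
        vmax = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
        cmap, vmin = plt.get_cmap("RdBu_r").copy(), -vmax
    else:
        cmap = plt.get_cmap("viridis").copy()
        vmin = vmax = None
    cmap.set_bad(MISSING_COLOR)
    im = ax.imshow(
        np.ma.masked_invalid(data),
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    from matplotlib.colors import to_rgba

    bar_rgba = np.array([[to_rgba(c)] for c in color_bar])
    ax_bar.imshow(bar_rgba, aspect="auto", interpolation="nearest")
    ax_bar.set_xticks([])
    ax_bar.set_yticks([])
    ax.set_yticks([])
    if len(col_labels) <= 40:
        ax.set_xticks(range(len(col_labels)))
        ax.set_xticklabels(col_labels, rotation=90, fontsize=6)
    else:
        ax.set_xticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    return fig


def embedding_scatter(
    embedding: Embedding, grouping: Grouping, dims: int = 2
) -> plt.Figure:
    """Static 2-D (components 1-2) or 3-D (components 1-3) scatter
    coloured by group, legend in grouping order."""
    if dims not in (2, 3):
        raise InputError("dims must be 2 or 3")
    if embedding.k < dims:
        raise InputError(
            f"embedding has {embedding.k} components, need at least {dims}"
        )
    coords = embedding.coords
    grouping.validate_against([str(i) for i in coords.index])
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d" if dims == 3 else None)
    for g in grouping.groups:
        cells = [c for c in coords.index if str(c) in g.members]
        pts = coords.loc[cells].to_numpy(dtype=float)
        if dims == 3:
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], color=g.color, label=g.label, s=12)
        else:
            ax.scatter(pts[:, 0], pts[:, 1], color=g.color, label=g.label, s=12)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if dims == 3:
        ax.set_zlabel(coords.columns[2])
    ax.legend(loc="best", fontsize=7)
    ax.set_title(f"{embedding.method} embedding")
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# scrapbook + report


def scrapbook_add(
    scrapbook: Scrapbook,
    fig: plt.Figure,
    annotation: str,
    workdir: Union[str, Path],
    name: str = "figure",
    timestamp: Optional[str] = None,
) -> ScrapbookEntry:
    """Save ``fig`` as PNG + SVG under ``workdir`` and append the PNG to
    the scrapbook with its annotation."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stem = workdir / f"{name}_{len(scrapbook) + 1:04d}"
    png = stem.with_suffix(".png")
    fig.savefig(png, dpi=100)
    fig.savefig(stem.with_suffix(".svg"))
    return scrapbook.add(png, annotation, timestamp=timestamp)


_REPORT_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
figure {{ border: 1px solid #ccc; padding: 1em; margin: 1em 0; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; font-size: 0.85em; }}
</style></head>
<body>
<h1>{title}</h1>
<p>{timestamp}</p>
<h2>Scrapbook</h2>
{figures}
<h2>Analysis log</h2>
<table>
<tr><th>#</th><th>operation</th><th>parameters</th><th>counts</th></tr>
{log_rows}
</table>
</body>
</html>
"""


def render_report(
    scrapbook: Scrapbook,
    log: AnalysisLog,
    path: Union[str, Path],
    title: str = "Analysis report",
    timestamp: str = "",
) -> Path:
    """Write an HTML report listing scrapbook entries in sequence order,
    followed by the full analysis log. Figure assets are written to a
    ``scrapbook/`` directory next to the report. Rendering is pure: the
    same state yields byte-identical HTML (timestamps are injected)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    assets = path.parent / "scrapbook"
    if scrapbook.asset_bytes:
        assets.mkdir(exist_ok=True)
        for name, payload in scrapbook.asset_bytes.items():
            (assets / name).write_bytes(payload)
    figures = []
    for e in scrapbook.entries:
        figures.append(
            f'<figure><img src="scrapbook/{html.escape(e.figure)}" width="600">'
            f"<figcaption>#{e.seq} {html.escape(e.annotation)}</figcaption></figure>"
        )
    log_rows = [
        "<tr><td>{}</td><td>{}</td><td>{}</td><td>{}</td></tr>".format(
            e.seq,
            html.escape(e.operation),
            html.escape(str(e.params)),
            html.escape(str(e.counts)),
        )
        for e in log
    ]
    text = _REPORT_TEMPLATE.format(
        title=html.escape(title),
        timestamp=html.escape(timestamp),
        figures="\n".join(figures) or "<p>(empty)</p>",
        log_rows="\n".join(log_rows),
    )
    path.write_text(text)
    return path
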