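"""Static figures with machine-readable companion tables.

Four figure types: volcano plots of one comparison, fold-change heatmaps
across comparisons, pathway-enrichment glyph grids (triangles/circles with
asterisks for both-direction hits), and force-directed network plots for
PPI networks and pathnets.

Every plotting function writes an image (PNG by default, SVG by extension)
and returns the companion table that encodes exactly what was drawn, so
each visual rule is testable without pixel comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import DEFAULT_FC_CUTOFF, DEFAULT_P_CUTOFF, select_degs
from .errors import ValidationError
from .io import DEGTable, GeneSetDatabase
from .pathnet import PathwayNetwork
from .ppi import PPINetwork

__all__ = [
    "VolcanoResult",
    "HeatmapResult",
    "GridResult",
    "NetworkPlotResult",
    "plot_volcano",
    "plot_foldchange_heatmap",
    "plot_pathway_grid",
    "plot_network",
    "export_interactive_html",
]


def _savefig(fig, out: str | Path, dpi: int = 300) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out


def _resolve_gene_list(
    genes: Sequence[str] | str | None, db: GeneSetDatabase | None
) -> set[str]:
    """A list of ids passes through; a string names a database set."""
    if genes is None:
        return set()
    if isinstance(genes, str):
        if db is None:
            raise ValidationError(
                f"{genes!r} looks like a set_id but no database was given"
            )
        return set(db[genes].genes)
    return set(genes)


# ---------------------------------------------------------------------------
# Volcano
# ---------------------------------------------------------------------------

@dataclass
class VolcanoResult:
    figure_path: Path
    n_up: int
    n_down: int
    n_ns: int
    companion: pd.DataFrame  # gene_id, log2_fc, p, neg_log10_p, class, highlighted, labeled


def plot_volcano(
    table: DEGTable,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    use_adjusted: bool = True,
    highlight: Sequence[str] | str | None = None,
    db: GeneSetDatabase | None = None,
    label_top_n: int = 10,
    log_fc_axis: bool = True,
    out: str | Path = "volcano.png",
) -> VolcanoResult:
    """Volcano plot: fold change vs -log10 significance.

    Points are classified up/down/non-significant by the same thresholds as
    DEG selection, and the up/down/ns counts appear in the subtitle.  Genes
    to highlight may be given as a list or as a set_id resolved against
    ``db``.  The top ``label_top_n`` genes by the product of the |fold
    change| rank and the significance rank are labelled.
    """
    if len(table) == 0:
        raise ValidationError("DEG table is empty")
    pcol = "p_adjusted" if use_adjusted else "p_value"
    df = table.data.copy()
    p = df[pcol].to_numpy(dtype=float)
    if (p == 0).any():
        warnings.warn(
            "p-values of exactly 0 replaced by the smallest positive float",
            stacklevel=2,
        )
        p = np.where(p == 0, np.nextafter(0.0, 1.0), p)
    df["p"] = p
    df["neg_log10_p"] = -np.log10(p)

    up, down = select_degs(table, p_cutoff, fc_cutoff, use_adjusted)
    cls = np.where(
        df["gene_id"].isin(up), "up",
        np.where(df["gene_id"].isin(down), "down", "ns"),
    )
    df["class"] = cls
    hl = _resolve_gene_list(highlight, db)
    df["highlighted"] = df["gene_id"].isin(hl)

    # label the strongest genes: best combined rank of effect and significance
    fc_rank = (-df["log2_fc"].abs()).rank(method="min")
    p_rank = (-df["neg_log10_p"]).rank(method="min")
    df["label_rank"] = fc_rank * p_rank
    sig = df[df["class"] != "ns"]
    labeled_ids = set(sig.nsmallest(label_top_n, "label_rank")["gene_id"])
    df["labeled"] = df["gene_id"].isin(labeled_ids)

    x = df["log2_fc"] if log_fc_axis else np.sign(df["log2_fc"]) * 2 ** df["log2_fc"].abs()
    colors = {"up": "#c0392b", "down": "#2980b9", "ns": "#bdbdbd"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in ("ns", "down", "up"):
        m = df["class"] == c
        ax.scatter(x[m], df.loc[m, "neg_log10_p"], s=8, c=colors[c], label=c)
    if hl.intersection(df["gene_id"]):
        m = df["highlighted"]
        ax.scatter(x[m], df.loc[m, "neg_log10_p"], s=26, facecolors="none",
                   edgecolors="black", linewidths=0.8)
    for row in df[df["labeled"]].itertuples():
        xi = row.log2_fc if log_fc_axis else np.sign(row.log2_fc) * 2 ** abs(row.log2_fc)
        ax.annotate(row.gene_id, (xi, row.neg_log10_p), fontsize=7)
    n_up, n_down, n_ns = len(up), len(down), len(df) - len(up) - len(down)
    ax.set_title(
        f"{table.comparison_name}\nup={n_up}  down={n_down}  ns={n_ns}",
        fontsize=10,
    )
    ax.set_xlabel("log2 fold change" if log_fc_axis else "fold change")
    ax.set_ylabel(f"-log10({pcol})")
    ax.axhline(-np.log10(p_cutoff), ls="--", lw=0.5, c="grey")
    for v in (fc_cutoff, -fc_cutoff):
        ax.axvline(v if log_fc_axis else np.sign(v) * 2 ** abs(v), ls="--", lw=0.5, c="grey")
    path = _savefig(fig, out)

    companion = df[
        ["gene_id", "log2_fc", "p", "neg_log10_p", "class", "highlighted", "labeled"]
    ].reset_index(drop=True)
    return VolcanoResult(path, n_up, n_down, n_ns, companion)


# ---------------------------------------------------------------------------
# Fold-change heatmap
# ---------------------------------------------------------------------------

@dataclass
class HeatmapResult:
    figure_path: Path
    matrix: pd.DataFrame  # genes x comparisons of log2_fc, NaN where unmeasured
    row_order: list[str]


def _nan_euclidean(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        return 0.0
    return float(np.sqrt(np.sum((a[ok] - b[ok]) ** 2)))


def plot_foldchange_heatmap(
    tables: Sequence[DEGTable],
    genes: Sequence[str] | str,
    db: GeneSetDatabase | None = None,
    cluster_rows: bool = False,
    out: str | Path = "heatmap.png",
) -> HeatmapResult:
    """Heatmap of log2 fold changes: genes as rows, comparisons as columns.

    Cells for genes absent from a comparison are missing (NaN), never zero.
    Optional row clustering uses complete linkage on euclidean distances
    with missing cells pairwise-excluded.
    """
    if not tables:
        raise ValidationError("need at least one DEG table")
    wanted = sorted(_resolve_gene_list(genes, db))
    if not wanted:
        raise ValidationError("no genes requested")
    cols = {}
    for t in tables:
        s = t.data.set_index("gene_id")["log2_fc"]
        cols[t.comparison_name] = s.reindex(wanted)
    matrix = pd.DataFrame(cols)
    found = matrix.dropna(how="all")
    if found.empty:
        raise ValidationError("none of the requested genes appear in any comparison")
    matrix = found

    order = list(matrix.index)
    if cluster_rows and len(matrix) > 2:
        from scipy.cluster.hierarchy import complete, leaves_list
        vals = matrix.to_numpy(dtype=float)
        m = len(vals)
        cond = np.array([
            _nan_euclidean(vals[i], vals[j])
            for i in range(m) for j in range(i + 1, m)
        ])
        order = [matrix.index[i] for i in leaves_list(complete(cond))]
        matrix = matrix.loc[order]

    fig, ax = plt.subplots(
        figsize=(1.2 + 0.7 * matrix.shape[1], 1.0 + 0.25 * matrix.shape[0])
    )
    vmax = np.nanmax(np.abs(matrix.to_numpy())) or 1.0
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto",
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right",
                  fontsize=8)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    path = _savefig(fig, out)
    return HeatmapResult(path, matrix, order)


# ---------------------------------------------------------------------------
# Pathway glyph grid
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    figure_path: Path
    glyphs: pd.DataFrame  # set_id, comparison, glyph, asterisk, p_adjusted_shown


_GLYPH_MARKERS = {"triangle_up": "^", "triangle_down": "v", "circle": "o"}


def compute_glyph_table(
    results: pd.DataFrame,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Resolve the glyph for every (pathway, comparison) cell.

    Rules: a pathway significant with direction ``all`` (no split) draws a
    circle; ``up``/``down`` draw a triangle pointing that way; significance
    in both directions draws the lower-p triangle plus an asterisk, showing
    the lower p.  Non-significant cells get glyph ``none``.
    """
    if results.empty:
        raise ValidationError("enrichment results are empty")
    res = results.copy()
    if categories is not None:
        res = res[res["category"].isin(set(categories))]
        if res.empty:
            raise ValidationError(
                f"category filter {list(categories)} removed every row"
            )
    sig = res[res["p_adjusted"] < p_cutoff]
    pathways = sorted(res["set_id"].unique())
    comparisons = list(dict.fromkeys(res["comparison"]))
    rows = []
    for sid in pathways:
        for comp in comparisons:
            cell = sig[(sig["set_id"] == sid) & (sig["comparison"] == comp)]
            if cell.empty:
                rows.append((sid, comp, "none", False, np.nan))
                continue
            dirs = set(cell["direction"])
            if dirs == {"all"}:
                best = cell.loc[cell["p_adjusted"].idxmin()]
                rows.append((sid, comp, "circle", False, best["p_adjusted"]))
            else:
                both = {"up", "down"} <= dirs
                best = cell.loc[cell["p_adjusted"].idxmin()]
                glyph = "triangle_up" if best["direction"] == "up" else "triangle_down"
                rows.append((sid, comp, glyph, both, best["p_adjusted"]))
    return pd.DataFrame(
        rows,
        columns=["set_id", "comparison", "glyph", "asterisk", "p_adjusted_shown"],
    )


def plot_pathway_grid(
    results: pd.DataFrame,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    categories: Sequence[str] | None = None,
    show_counts: bool = False,
    deg_counts: dict[str, int] | None = None,
    out: str | Path = "pathway_grid.png",
) -> GridResult:
    """Grid of enrichment glyphs: comparisons as columns, pathways as rows.

    Rows are sorted alphabetically by name within category groups.  With
    ``show_counts`` the number of DEGs (from ``deg_counts``) is appended
    under each comparison name.
    """
    glyphs = compute_glyph_table(results, p_cutoff, categories)
    shown = glyphs[glyphs["glyph"] != "none"]
    if shown.empty:
        raise ValidationError("no significant pathway in any comparison")
    meta = results.drop_duplicates("set_id").set_index("set_id")
    keep = sorted(
        shown["set_id"].unique(),
        key=lambda sid: (
            str(meta.loc[sid].get("category") or "~"),
            str(meta.loc[sid]["set_name"]),
        ),
    )
    comparisons = list(dict.fromkeys(results["comparison"]))
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.9 * len(comparisons), 1.0 + 0.3 * len(keep))
    )
    pvals = shown["p_adjusted_shown"]
    for yi, sid in enumerate(keep):
        for xi, comp in enumerate(comparisons):
            cell = glyphs[(glyphs["set_id"] == sid) & (glyphs["comparison"] == comp)]
            if cell.empty or cell.iloc[0]["glyph"] == "none":
                continue
            row = cell.iloc[0]
            size = 40 + 60 * (
                -np.log10(max(row["p_adjusted_shown"], 1e-300))
                / max(-np.log10(max(pvals.min(), 1e-300)), 1.0)
            )
            color = {"triangle_up": "#c0392b", "triangle_down": "#2980b9",
                     "circle": "#7f8c8d"}[row["glyph"]]
            ax.scatter(xi, yi, marker=_GLYPH_MARKERS[row["glyph"]], s=size, c=color)
            if row["asterisk"]:
                ax.annotate("*", (xi + 0.18, yi + 0.1), fontsize=10)
    labels = []
    for comp in comparisons:
        lab = comp
        if show_counts and deg_counts and comp in deg_counts:
            lab += f"\n(n={deg_counts[comp]})"
        labels.append(lab)
    ax.set_xticks(range(len(comparisons)), labels, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(
        range(len(keep)),
        [str(meta.loc[s]["set_name"]) for s in keep],
        fontsize=7,
    )
    ax.set_xlim(-0.5, len(comparisons) - 0.5)
    ax.set_ylim(-0.5, len(keep) - 0.5)
    ax.invert_yaxis()
    path = _savefig(fig, out)
    return GridResult(path, glyphs)


# ---------------------------------------------------------------------------
# Network plot
# ---------------------------------------------------------------------------

@dataclass
class NetworkPlotResult:
    figure_path: Path
    coordinates: pd.DataFrame  # node, x, y
    n_nodes: int


def plot_network(
    network: PPINetwork | PathwayNetwork,
    color_by: str | None = None,
    layout_seed: int = 0,
    out: str | Path = "network.png",
) -> NetworkPlotResult:
    """Force-directed plot; layout deterministic under ``layout_seed``.

    ``color_by`` names an existing node attribute mapped to colour.  Hubs
    (when scored) are labelled; pathnet nodes are filled when enriched and
    hollow otherwise, coloured by category.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    if color_by is not None:
        available = sorted({k for _, a in g.nodes(data=True) for k in a})
        if not any(color_by in a for _, a in g.nodes(data=True)):
            raise ValidationError(
                f"unknown node attribute {color_by!r}; available: {available}"
            )
    nodes = sorted(g.nodes)
    pos = nx.spring_layout(g, seed=layout_seed)
    coords = pd.DataFrame(
        [(v, float(pos[v][0]), float(pos[v][1])) for v in nodes],
        columns=["node", "x", "y"],
    )

    fig, ax = plt.subplots(figsize=(6, 6))
    is_pathnet = isinstance(network, PathwayNetwork)
    if color_by is not None:
        vals = [g.nodes[v].get(color_by) for v in nodes]
        if all(isinstance(v, (int, float)) or v is None for v in vals):
            arr = np.array([np.nan if v is None else float(v) for v in vals])
            colors = plt.cm.coolwarm(
                (arr - np.nanmin(arr)) / ((np.nanmax(arr) - np.nanmin(arr)) or 1.0)
            )
        else:
            cats = sorted({str(v) for v in vals})
            cmap = plt.cm.tab10
            colors = [cmap(cats.index(str(v)) % 10) for v in vals]
    elif is_pathnet:
        cats = sorted({str(g.nodes[v].get("category")) for v in nodes})
        colors = [plt.cm.tab10(cats.index(str(g.nodes[v].get("category"))) % 10)
                  for v in nodes]
    else:
        colors = ["#5dade2"] * len(nodes)

    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.3, width=0.5)
    if is_pathnet:
        filled = [v for v in nodes if g.nodes[v].get("enriched")]
        hollow = [v for v in nodes if not g.nodes[v].get("enriched")]
        cmap_of = dict(zip(nodes, colors))
        nx.draw_networkx_nodes(
            g, pos, nodelist=filled, ax=ax, node_size=120,
            node_color=[cmap_of[v] for v in filled],
        )
        nx.draw_networkx_nodes(
            g, pos, nodelist=hollow, ax=ax, node_size=120, node_color="white",
            edgecolors=[cmap_of[v] for v in hollow], linewidths=1.5,
        )
    else:
        nx.draw_networkx_nodes(g, pos, nodelist=nodes, ax=ax, node_size=60,
                               node_color=colors)
        hubs = [v for v in nodes if g.nodes[v].get("is_hub")]
        if hubs:
            nx.draw_networkx_labels(
                g, pos, labels={v: v for v in hubs}, ax=ax, font_size=8,
                font_weight="bold",
            )
    ax.set_axis_off()
    path = _savefig(fig, out)
    return NetworkPlotResult(path, coords, len(nodes))


def export_interactive_html(
    network: PPINetwork | PathwayNetwork,
    out: str | Path,
    layout_seed: int = 0,
) -> Path:
    """Experimental: dump a self-contained HTML page listing the network.

    A placeholder for interactive exploration; renders a static coordinate
    table only and is not part of the stable interface.
    """
    g = network.graph
    pos = nx.spring_layout(g, seed=layout_seed)
    rows = "\n".join(
        f"<tr><td>{v}</td><td>{pos[v][0]:.4f}</td><td>{pos[v][1]:.4f}</td></tr>"
        for v in sorted(g.nodes)
    )
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>network (experimental export)</title></head><body>"
        f"<p>{g.number_of_nodes()} nodes, {g.number_of_edges()} edges</p>"
        f"<table><tr><th>node</th><th>x</th><th>y</th></tr>{rows}</table>"
        "</body></html>"
    )
    out = Path(out)
    out.write_text(html, encoding="utf-8")
    return out
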